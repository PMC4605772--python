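# klinfo circuit parameter file
N = 78
M = 100
tau = 0.2693472671082799
w_ON_AIYL = 421.682888738359
w_ON_AIYR = -15.605472413972791
w_OFF_AIYL = -500.0
w_OFF_AIYR = -62.42887588175353
w_AIYL_AIZL = -1.5917041808544177
w_AIYR_AIZR = 10.560584121757564
w_AIZL_SMBDL = 15.0
w_AIZL_SMBVL = 15.0
w_AIZR_SMBDR = 12.669333642405029
w_AIZR_SMBVR = 12.669333642405029
w_SMBDL_self = -2.5591223064000097
w_SMBDR_self = -10.964501031427684
w_SMBVL_self = -2.5591223064000097
w_SMBVR_self = -10.964501031427684
g_AIY = 1.1276115305631607
g_AIZ = 0.01
theta_AIYL = 11.15148254432129
theta_AIYR = -0.28389323770477404
theta_AIZL = 1.7369465012795366
theta_AIZR = -4.302267091506685
theta_SMBDL = 7.891333438643599
theta_SMBDR = 5.966628735251433
theta_SMBVL = 7.891333438643599
theta_SMBVR = 5.966628735251433
w_PG = 8.889776911541844
w_NMJ = -2.1596682408972745
T = 4.2
v = 0.022
dv_symmetric = True
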