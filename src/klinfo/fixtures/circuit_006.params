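# klinfo circuit parameter file
N = 37
M = 57
tau = 0.1
w_ON_AIYL = 343.8465434336297
w_ON_AIYR = 223.59260898333264
w_OFF_AIYL = -62.11177529715212
w_OFF_AIYR = -500.0
w_AIYL_AIZL = -11.88272488674082
w_AIYR_AIZR = 15.0
w_AIZL_SMBDL = -10.91288943570978
w_AIZL_SMBVL = -10.91288943570978
w_AIZR_SMBDR = -9.698308716509032
w_AIZR_SMBVR = -9.698308716509032
w_SMBDL_self = -13.166434796805234
w_SMBDR_self = -3.372674619332555
w_SMBVL_self = -13.166434796805234
w_SMBVR_self = -3.372674619332555
g_AIY = 1.9181005141512446
g_AIZ = 0.42217711850525275
theta_AIYL = 7.843654045772059
theta_AIYR = -1.3486612618930067
theta_AIZL = -15.0
theta_AIZR = 0.41235860586444417
theta_SMBDL = -6.4062115523458765
theta_SMBDR = -0.44837273821337575
theta_SMBVL = -6.4062115523458765
theta_SMBVR = -0.44837273821337575
w_PG = -7.730833633971822
w_NMJ = 2.627105509636925
T = 4.2
v = 0.022
dv_symmetric = True
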