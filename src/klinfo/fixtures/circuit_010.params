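# klinfo circuit parameter file
N = 75
M = 5
tau = 0.24266818602861112
w_ON_AIYL = 264.15641076413146
w_ON_AIYR = -384.71729378101463
w_OFF_AIYL = 500.0
w_OFF_AIYR = 192.60405754098815
w_AIYL_AIZL = -11.607101977809112
w_AIYR_AIZR = 12.40362737022194
w_AIZL_SMBDL = 9.575810726332147
w_AIZL_SMBVL = 9.575810726332147
w_AIZR_SMBDR = 14.308773488036856
w_AIZR_SMBVR = 14.308773488036856
w_SMBDL_self = 15.0
w_SMBDR_self = -11.150676764578321
w_SMBVL_self = 15.0
w_SMBVR_self = -11.150676764578321
g_AIY = 2.490453049529568
g_AIZ = 1.650330912273135
theta_AIYL = -8.42948757416291
theta_AIYR = -0.47448662051968604
theta_AIZL = -1.96930458496416
theta_AIZR = -3.0752055826008533
theta_SMBDL = 15.0
theta_SMBDR = -9.175900673308675
theta_SMBVL = 15.0
theta_SMBVR = -9.175900673308675
w_PG = -8.553803657648594
w_NMJ = 2.9177434687132955
T = 4.2
v = 0.022
dv_symmetric = True
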