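# klinfo circuit parameter file
N = 59
M = 82
tau = 0.17696320570699875
w_ON_AIYL = 123.86736756323228
w_ON_AIYR = -345.45127498745376
w_OFF_AIYL = 500.0
w_OFF_AIYR = 171.61536939323628
w_AIYL_AIZL = -1.5111984426087286
w_AIYR_AIZR = -15.0
w_AIZL_SMBDL = 7.167621758054029
w_AIZL_SMBVL = 7.167621758054029
w_AIZR_SMBDR = -14.810748747564991
w_AIZR_SMBVR = -14.810748747564991
w_SMBDL_self = -1.0124138847746789
w_SMBDR_self = -7.31698824296236
w_SMBVL_self = -1.0124138847746789
w_SMBVR_self = -7.31698824296236
g_AIY = 1.0761537361981628
g_AIZ = 1.163318167202788
theta_AIYL = 7.179905719044825
theta_AIYR = -0.09076382334345467
theta_AIZL = -7.2873068117441155
theta_AIZR = 4.8316082817271315
theta_SMBDL = -14.349511749768077
theta_SMBDR = 6.119537542048892
theta_SMBVL = -14.349511749768077
theta_SMBVR = 6.119537542048892
w_PG = 9.815739240093013
w_NMJ = -3.0
T = 4.2
v = 0.022
dv_symmetric = True
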