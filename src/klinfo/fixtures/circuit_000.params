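# klinfo circuit parameter file
N = 105
M = 38
tau = 0.3353569243140625
w_ON_AIYL = 383.8438935559624
w_ON_AIYR = 326.626115836943
w_OFF_AIYL = -500.0
w_OFF_AIYR = 134.5251891461328
w_AIYL_AIZL = -15.0
w_AIYR_AIZR = 5.364292798919312
w_AIZL_SMBDL = 12.62880765641896
w_AIZL_SMBVL = 12.62880765641896
w_AIZR_SMBDR = -11.743192519399438
w_AIZR_SMBVR = -11.743192519399438
w_SMBDL_self = -5.223223196041451
w_SMBDR_self = -13.59943652288046
w_SMBVL_self = -5.223223196041451
w_SMBVR_self = -13.59943652288046
g_AIY = 1.0484826074938294
g_AIZ = 2.1602619735524997
theta_AIYL = 0.6198466201290547
theta_AIYR = 0.7636107221315882
theta_AIZL = 5.414426702103533
theta_AIZR = 12.363723289005218
theta_SMBDL = -9.256832165524989
theta_SMBDR = 0.5966930075000398
theta_SMBVL = -9.256832165524989
theta_SMBVR = 0.5966930075000398
w_PG = -7.92958403849632
w_NMJ = 2.8062406318386524
T = 4.2
v = 0.022
dv_symmetric = True
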