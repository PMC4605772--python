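# klinfo circuit parameter file
N = 64
M = 90
tau = 0.3743304665513558
w_ON_AIYL = -420.8700528831271
w_ON_AIYR = -421.2508706711347
w_OFF_AIYL = 303.7724604826782
w_OFF_AIYR = 434.38103328688703
w_AIYL_AIZL = 4.82176273409468
w_AIYR_AIZR = 15.0
w_AIZL_SMBDL = 15.0
w_AIZL_SMBVL = 15.0
w_AIZR_SMBDR = 9.359821130456318
w_AIZR_SMBVR = 9.359821130456318
w_SMBDL_self = -13.722410360706773
w_SMBDR_self = -14.184827526459816
w_SMBVL_self = -13.722410360706773
w_SMBVR_self = -14.184827526459816
g_AIY = 1.7636843791729995
g_AIZ = 1.1961274900722696
theta_AIYL = 2.1326812747045807
theta_AIYR = -0.8878782386936521
theta_AIZL = -3.5212029065713732
theta_AIZR = -5.755490897621863
theta_SMBDL = -9.862378721920717
theta_SMBDR = -10.625632071841434
theta_SMBVL = -9.862378721920717
theta_SMBVR = -10.625632071841434
w_PG = 7.9528532197008985
w_NMJ = -2.819719952269322
T = 4.2
v = 0.022
dv_symmetric = True
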