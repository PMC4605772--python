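# klinfo circuit parameter file
N = 57
M = 95
tau = 0.1334361025385985
w_ON_AIYL = 500.0
w_ON_AIYR = 336.6044614544388
w_OFF_AIYL = -500.0
w_OFF_AIYR = 236.7410400957532
w_AIYL_AIZL = 8.600676226561326
w_AIYR_AIZR = 10.042326502920012
w_AIZL_SMBDL = -10.007047988940148
w_AIZL_SMBVL = -10.007047988940148
w_AIZR_SMBDR = 4.668133390049054
w_AIZR_SMBVR = 4.668133390049054
w_SMBDL_self = -7.761282833349926
w_SMBDR_self = -13.41948675335613
w_SMBVL_self = -7.761282833349926
w_SMBVR_self = -13.41948675335613
g_AIY = 2.261921932142761
g_AIZ = 0.2627803748349833
theta_AIYL = 0.396020641780817
theta_AIYR = -3.1698169652699377
theta_AIZL = -4.501041718354617
theta_AIZR = -12.265194516637301
theta_SMBDL = 0.7298671117967288
theta_SMBDR = -6.374760128345045
theta_SMBVL = 0.7298671117967288
theta_SMBVR = -6.374760128345045
w_PG = -7.436815142891592
w_NMJ = 2.954461105586729
T = 4.2
v = 0.022
dv_symmetric = True
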