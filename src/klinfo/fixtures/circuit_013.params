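# klinfo circuit parameter file
N = 42
M = 84
tau = 0.1
w_ON_AIYL = -434.77973392102587
w_ON_AIYR = -93.46841655710745
w_OFF_AIYL = 482.04612345942076
w_OFF_AIYR = 247.23751914505942
w_AIYL_AIZL = 7.564241213664214
w_AIYR_AIZR = 10.542167222458666
w_AIZL_SMBDL = 15.0
w_AIZL_SMBVL = 15.0
w_AIZR_SMBDR = -11.6396327001147
w_AIZR_SMBVR = -11.6396327001147
w_SMBDL_self = 15.0
w_SMBDR_self = -1.5711928838951525
w_SMBVL_self = 15.0
w_SMBVR_self = -1.5711928838951525
g_AIY = 1.762816315007287
g_AIZ = 0.13881036720880635
theta_AIYL = 5.546367257903796
theta_AIYR = -0.966925467334633
theta_AIZL = 10.745391590492716
theta_AIZR = -2.763375666137719
theta_SMBDL = 7.9819613171210335
theta_SMBDR = 14.648014346571255
theta_SMBVL = 7.9819613171210335
theta_SMBVR = 14.648014346571255
w_PG = 8.998550222928362
w_NMJ = -2.5860058206962244
T = 4.2
v = 0.022
dv_symmetric = True
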