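# klinfo circuit parameter file
N = 6
M = 83
tau = 0.22053216692301766
w_ON_AIYL = 348.1445579333846
w_ON_AIYR = 500.0
w_OFF_AIYL = -430.1243225267422
w_OFF_AIYR = -351.4174308451318
w_AIYL_AIZL = -3.49106980282364
w_AIYR_AIZR = -11.567596128179684
w_AIZL_SMBDL = -7.743576056425617
w_AIZL_SMBVL = -7.743576056425617
w_AIZR_SMBDR = -10.38141687380513
w_AIZR_SMBVR = -10.38141687380513
w_SMBDL_self = 5.051952587158571
w_SMBDR_self = -0.24511039856138161
w_SMBVL_self = 5.051952587158571
w_SMBVR_self = -0.24511039856138161
g_AIY = 2.3209617323109613
g_AIZ = 2.1981281188058603
theta_AIYL = -4.105854151289568
theta_AIYR = -1.1679096909602436
theta_AIZL = 2.8158624300862094
theta_AIZR = 2.8771649298344073
theta_SMBDL = -8.6858069263299
theta_SMBDR = 14.783597535606141
theta_SMBVL = -8.6858069263299
theta_SMBVR = 14.783597535606141
w_PG = -8.065561507113454
w_NMJ = 3.0
T = 4.2
v = 0.022
dv_symmetric = True
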