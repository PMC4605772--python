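# klinfo circuit parameter file
N = 56
M = 42
tau = 0.15504361719769863
w_ON_AIYL = -474.4648317894197
w_ON_AIYR = -394.2095327648062
w_OFF_AIYL = 500.0
w_OFF_AIYR = -10.835224845327446
w_AIYL_AIZL = -8.943033285835336
w_AIYR_AIZR = -13.59797261835715
w_AIZL_SMBDL = 9.18386416651363
w_AIZL_SMBVL = 9.18386416651363
w_AIZR_SMBDR = 14.217211133749462
w_AIZR_SMBVR = 14.217211133749462
w_SMBDL_self = 0.4699553545142603
w_SMBDR_self = 4.747101219096642
w_SMBVL_self = 0.4699553545142603
w_SMBVR_self = 4.747101219096642
g_AIY = 1.8626133887307563
g_AIZ = 0.3398974145404318
theta_AIYL = -2.4137411094956978
theta_AIYR = -0.3744733339006263
theta_AIZL = -5.922244426162365
theta_AIZR = 6.302180298572182
theta_SMBDL = 13.611547675572627
theta_SMBDR = -6.8417691666335845
theta_SMBVL = 13.611547675572627
theta_SMBVR = -6.8417691666335845
w_PG = 10.0
w_NMJ = -2.0753826115126133
T = 4.2
v = 0.022
dv_symmetric = True
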