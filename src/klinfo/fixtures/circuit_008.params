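# klinfo circuit parameter file
N = 96
M = 90
tau = 0.1
w_ON_AIYL = 126.79395435932759
w_ON_AIYR = -444.84740523599186
w_OFF_AIYL = 241.89313869163993
w_OFF_AIYR = -159.1896496602307
w_AIYL_AIZL = 15.0
w_AIYR_AIZR = -3.9285760133961283
w_AIZL_SMBDL = -8.011415714259403
w_AIZL_SMBVL = -8.011415714259403
w_AIZR_SMBDR = -14.1918015299022
w_AIZR_SMBVR = -14.1918015299022
w_SMBDL_self = -10.10069312592271
w_SMBDR_self = -9.150524488398172
w_SMBVL_self = -10.10069312592271
w_SMBVR_self = -9.150524488398172
g_AIY = 1.9414525439612262
g_AIZ = 1.3098607435226184
theta_AIYL = 0.19446555096916107
theta_AIYR = -12.994676847870643
theta_AIZL = -5.391481187835824
theta_AIZR = -15.0
theta_SMBDL = 14.443792837618897
theta_SMBDR = -7.939881790902198
theta_SMBVL = 14.443792837618897
theta_SMBVR = -7.939881790902198
w_PG = -6.918497014121421
w_NMJ = 3.0
T = 4.2
v = 0.022
dv_symmetric = True
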