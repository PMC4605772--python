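# klinfo circuit parameter file
N = 103
M = 88
tau = 0.1
w_ON_AIYL = -486.4225632711955
w_ON_AIYR = 399.4889405715421
w_OFF_AIYL = 93.91359639119764
w_OFF_AIYR = 43.74265741676413
w_AIYL_AIZL = 15.0
w_AIYR_AIZR = -0.25504609717619253
w_AIZL_SMBDL = 14.375212728238495
w_AIZL_SMBVL = 14.375212728238495
w_AIZR_SMBDR = 0.9464697558111048
w_AIZR_SMBVR = 0.9464697558111048
w_SMBDL_self = 5.456914045765252
w_SMBDR_self = -14.399499933671253
w_SMBVL_self = 5.456914045765252
w_SMBVR_self = -14.399499933671253
g_AIY = 0.7273284879411507
g_AIZ = 0.01
theta_AIYL = 2.349232646822397
theta_AIYR = -2.08931180530878
theta_AIZL = -13.30364670513879
theta_AIZR = 0.14152718679304854
theta_SMBDL = -13.28135746039411
theta_SMBDR = 2.389470615726932
theta_SMBVL = -13.28135746039411
theta_SMBVR = 2.389470615726932
w_PG = -7.672610925825668
w_NMJ = 1.4982423380190433
T = 4.2
v = 0.022
dv_symmetric = True
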