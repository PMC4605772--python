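# klinfo circuit parameter file
N = 27
M = 95
tau = 0.2189658493519265
w_ON_AIYL = -298.04752916966953
w_ON_AIYR = -10.358130642908861
w_OFF_AIYL = 238.13348772392715
w_OFF_AIYR = 499.80733631346686
w_AIYL_AIZL = 5.873159372388411
w_AIYR_AIZR = 15.0
w_AIZL_SMBDL = -2.1776431466723025
w_AIZL_SMBVL = -2.1776431466723025
w_AIZR_SMBDR = -13.557354106489901
w_AIZR_SMBVR = -13.557354106489901
w_SMBDL_self = -2.546143382033252
w_SMBDR_self = 8.223053966714684
w_SMBVL_self = -2.546143382033252
w_SMBVR_self = 8.223053966714684
g_AIY = 1.9154144279792504
g_AIZ = 0.8014730675113297
theta_AIYL = -1.5504963941995076
theta_AIYR = 2.823643246450615
theta_AIZL = -8.811423117005681
theta_AIZR = -11.086929177868365
theta_SMBDL = 6.792369897188696
theta_SMBDR = 1.8096463626172437
theta_SMBVL = 6.792369897188696
theta_SMBVR = 1.8096463626172437
w_PG = -4.659579717064202
w_NMJ = 2.388045838281532
T = 4.2
v = 0.022
dv_symmetric = True
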