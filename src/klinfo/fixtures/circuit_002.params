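# klinfo circuit parameter file
N = 56
M = 20
tau = 0.16257305688084767
w_ON_AIYL = -123.95103123949212
w_ON_AIYR = -232.46789637928214
w_OFF_AIYL = -274.0741196734861
w_OFF_AIYR = 404.99184865228676
w_AIYL_AIZL = -1.791417669896303
w_AIYR_AIZR = -5.417251390878205
w_AIZL_SMBDL = 14.869373208104939
w_AIZL_SMBVL = 14.869373208104939
w_AIZR_SMBDR = -15.0
w_AIZR_SMBVR = -15.0
w_SMBDL_self = -9.205763501806363
w_SMBDR_self = -12.89534068013402
w_SMBVL_self = -9.205763501806363
w_SMBVR_self = -12.89534068013402
g_AIY = 0.01
g_AIZ = 0.012027453026071453
theta_AIYL = 15.0
theta_AIYR = -0.9687972403059941
theta_AIZL = 11.760795962873512
theta_AIZR = 0.20908533462695544
theta_SMBDL = -6.242342066219415
theta_SMBDR = -4.383227185034469
theta_SMBVL = -6.242342066219415
theta_SMBVR = -4.383227185034469
w_PG = -6.699344401385698
w_NMJ = 2.532369970808629
T = 4.2
v = 0.022
dv_symmetric = True
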