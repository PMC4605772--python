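# klinfo circuit parameter file
N = 105
M = 85
tau = 0.1
w_ON_AIYL = 355.6382062157073
w_ON_AIYR = -390.80521870803966
w_OFF_AIYL = 170.4983400549254
w_OFF_AIYR = 500.0
w_AIYL_AIZL = 4.660825171143074
w_AIYR_AIZR = 8.719151836956954
w_AIZL_SMBDL = -15.0
w_AIZL_SMBVL = -15.0
w_AIZR_SMBDR = 8.434629874689328
w_AIZR_SMBVR = 8.434629874689328
w_SMBDL_self = -7.764108703922922
w_SMBDR_self = -0.447162722026226
w_SMBVL_self = -7.764108703922922
w_SMBVR_self = -0.447162722026226
g_AIY = 1.9188166773962791
g_AIZ = 0.3375022817996595
theta_AIYL = -9.614146325970331
theta_AIYR = -0.5146740976857238
theta_AIZL = 9.604740492677884
theta_AIZR = -2.0786954404852374
theta_SMBDL = 1.2140691085358206
theta_SMBDR = -13.00090838867371
theta_SMBVL = 1.2140691085358206
theta_SMBVR = -13.00090838867371
w_PG = 10.0
w_NMJ = -2.226447044696687
T = 4.2
v = 0.022
dv_symmetric = True
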