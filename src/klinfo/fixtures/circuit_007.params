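# klinfo circuit parameter file
N = 92
M = 25
tau = 0.1
w_ON_AIYL = 500.0
w_ON_AIYR = 401.6650189142557
w_OFF_AIYL = 84.66285632502388
w_OFF_AIYR = -449.8435559266464
w_AIYL_AIZL = -3.749797882713729
w_AIYR_AIZR = 14.559237539821375
w_AIZL_SMBDL = 13.388774277750628
w_AIZL_SMBVL = 13.388774277750628
w_AIZR_SMBDR = 11.58964686605271
w_AIZR_SMBVR = 11.58964686605271
w_SMBDL_self = -11.084447139603459
w_SMBDR_self = -0.41703160532377836
w_SMBVL_self = -11.084447139603459
w_SMBVR_self = -0.41703160532377836
g_AIY = 2.158128793221544
g_AIZ = 1.140375592482455
theta_AIYL = 15.0
theta_AIYR = -0.8642676300679799
theta_AIZL = -8.042848651996579
theta_AIZR = -2.7598073674548598
theta_SMBDL = 13.067914036448741
theta_SMBDR = 0.14843666936257982
theta_SMBVL = 13.067914036448741
theta_SMBVR = 0.14843666936257982
w_PG = 4.329275476733335
w_NMJ = -1.7438760374727895
T = 4.2
v = 0.022
dv_symmetric = True
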