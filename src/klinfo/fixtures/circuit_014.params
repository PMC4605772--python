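# klinfo circuit parameter file
N = 42
M = 102
tau = 0.1
w_ON_AIYL = -177.12943997516686
w_ON_AIYR = 500.0
w_OFF_AIYL = -241.37260264587985
w_OFF_AIYR = -479.9029578616053
w_AIYL_AIZL = -9.991530065465515
w_AIYR_AIZR = -3.32586324276941
w_AIZL_SMBDL = 8.233406616141636
w_AIZL_SMBVL = 8.233406616141636
w_AIZR_SMBDR = 9.927531353156262
w_AIZR_SMBVR = 9.927531353156262
w_SMBDL_self = 4.363532354688136
w_SMBDR_self = -11.011942325728484
w_SMBVL_self = 4.363532354688136
w_SMBVR_self = -11.011942325728484
g_AIY = 1.105510674181581
g_AIZ = 2.5
theta_AIYL = 7.782926982817742
theta_AIYR = -0.653460028866581
theta_AIZL = 5.131996722442096
theta_AIZR = 2.199605072145026
theta_SMBDL = -5.934850605603819
theta_SMBDR = 1.3802031602790272
theta_SMBVL = -5.934850605603819
theta_SMBVR = 1.3802031602790272
w_PG = -1.5254500473888868
w_NMJ = 2.6682796177007075
T = 4.2
v = 0.022
dv_symmetric = True
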