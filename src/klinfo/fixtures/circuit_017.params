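# klinfo circuit parameter file
N = 91
M = 26
tau = 0.2701541992818638
w_ON_AIYL = -422.59866057122633
w_ON_AIYR = 65.27846999647306
w_OFF_AIYL = 500.0
w_OFF_AIYR = 245.87095650912966
w_AIYL_AIZL = -8.986363438715834
w_AIYR_AIZR = 3.2621552161246257
w_AIZL_SMBDL = 13.458865308977256
w_AIZL_SMBVL = 13.458865308977256
w_AIZR_SMBDR = -11.258305040374417
w_AIZR_SMBVR = -11.258305040374417
w_SMBDL_self = -13.089678764906957
w_SMBDR_self = 8.853261768955644
w_SMBVL_self = -13.089678764906957
w_SMBVR_self = 8.853261768955644
g_AIY = 0.8604903775045727
g_AIZ = 2.1170199874445608
theta_AIYL = 0.7699113230974106
theta_AIYR = 10.331620234376825
theta_AIZL = 2.6056521861370676
theta_AIZR = 1.3577016947752476
theta_SMBDL = 7.701518013167917
theta_SMBDR = 0.2055235471817678
theta_SMBVL = 7.701518013167917
theta_SMBVR = 0.2055235471817678
w_PG = 8.202254990186276
w_NMJ = -1.708483659369828
T = 4.2
v = 0.022
dv_symmetric = True
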