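Ng = 3080000000.0
Q = 3804.0
A0 = 13100000000.0
tau = 1320.0
Nq = 431.0
NQ = 1300.0
NL = 6000.0
NS = 300.0
Naa = 5.0
Nnt = 15.0
chi_maxL = 840.0
chi_maxS = 840.0
K_chiL = 11000000.0
K_chiS = 11000000.0
K_L = 0.00224
w_q = 4.64
w_L = 1.0
w_S = 20.0
theta_q = 3800000000.0
theta_L = 3800000000.0
theta_S = 3800000000.0
gamma_maxq = 300.0
gamma_maxL = 300.0
K_gammaq = 25900.0
K_gammaL = 25900.0
k_bq = 5e-08
k_bL = 5e-08
k_uq = 0.01
k_uL = 0.01
k_subS = 5e-08
k_subL = 5e-06
r_tot = 9500000.0
lambda_a = 1.47
d_mq = 0.00115
d_mL = 0.00115
d_mS = 0.00115
d_cq = 0.00155
d_cL = 0.00155
d_q = 0.000567
d_O1 = 0.000567
d_bL = 0.000567
d_bS = 0.000567
lambda_L = 0.37
lambda_S = 1.18
V_cell = 3700.0
a_wt = 5330000000.0
L_wt = 1064.0
S_wt = 13243.0
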