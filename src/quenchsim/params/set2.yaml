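# Parameter Set 2: faster degradation rates and higher operating
# concentrations so that every steady-state abundance stays at or above
# 4 molecules per cell, making the set suitable for discrete stochastic
# simulation (synthetic reconstruction).  The total LuxR pool is pinned
# at 12 molecules per cell.  Units: nM, hours, um.
model: full
description: quenched repressilator, stochastic-simulation regime
n_C: 4
k_C: 192.0
l_C: 0.002
n_TO: 4
k_TO: 192.0
l_TO: 0.002
n_TQ: 4
k_TQ: 432.0
l_TQ: 0.002
n_L: 4
k_L: 192.0
l_L: 0.002
n_I: 4
k_I: 192.0
l_I: 0.002
K_C: 96.0
K_T: 96.0
K_L: 96.0
K_RA: 7.2
K_R: 100.0
h_C: 2.0
h_T: 2.0
h_L: 2.0
h_RA: 2.0
g_mC: 6.0
g_mTO: 6.0
g_mTQ: 15.0
g_mL: 6.0
g_mI: 15.0
g_pC: 3.0
g_pT: 3.0
g_pL: 3.0
g_pI: 10.0
g_A: 10.0
a_C: 30.0
a_T: 30.0
a_L: 30.0
a_I: 30.0
k_A: 5.0
R_T: 19.92648912
C: 1.66054
D_A: 5000.0
L: 100.0
cell_edge: 1.0
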