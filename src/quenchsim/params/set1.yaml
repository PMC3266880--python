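# Parameter Set 1: literature-style kinetics for the repressilator +
# lux quenching loop, PDE-simulation regime (synthetic reconstruction).
# Several steady-state concentrations fall near or below one molecule
# per cell (~1.66 nM), so this set is suitable for deterministic
# simulation only.  Units: nM, hours, um.
model: full
description: quenched repressilator, deterministic (PDE) regime
n_C: 4
k_C: 20.0
l_C: 0.002
n_TO: 4
k_TO: 20.0
l_TO: 0.002
n_TQ: 4
k_TQ: 20.0
l_TQ: 0.002
n_L: 4
k_L: 20.0
l_L: 0.002
n_I: 4
k_I: 20.0
l_I: 0.002
K_C: 20.0
K_T: 20.0
K_L: 20.0
K_RA: 1.0
K_R: 100.0
h_C: 2.0
h_T: 2.0
h_L: 2.0
h_RA: 2.0
g_mC: 3.0
g_mTO: 3.0
g_mTQ: 7.5
g_mL: 3.0
g_mI: 7.5
g_pC: 1.5
g_pT: 1.5
g_pL: 1.5
g_pI: 5.0
g_A: 5.0
a_C: 15.0
a_T: 15.0
a_L: 15.0
a_I: 15.0
k_A: 2.5
R_T: 19.92648912
C: 1.66054
D_A: 5000.0
L: 100.0
cell_edge: 1.0
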