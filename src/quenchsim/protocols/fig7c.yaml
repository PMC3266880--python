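# Parameter Set 2, single cell, stochastic, no diffusion: small-amplitude
# sustained oscillations with occasional firing events.
name: fig7c
model: full
params: set2
simulator: ssa
geometry: single_cell
diffusion: false
n_empty_side: 25
t_end: 40.0
record_dt: 0.02
seed: 1
analysis_species: [cI]
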