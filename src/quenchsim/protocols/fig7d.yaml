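# Parameter Set 2, single cell, stochastic, AHL diffusing away: larger,
# irregular oscillations; period longer than without diffusion.
name: fig7d
model: full
params: set2
simulator: ssa
geometry: single_cell
diffusion: true
n_empty_side: 25
t_end: 40.0
record_dt: 0.02
seed: 1
analysis_species: [cI]
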