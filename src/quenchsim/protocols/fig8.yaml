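# Parameter Set 2, 100-cell line, stochastic, homogeneous start: noise
# excites the unstable wave numbers and patterning emerges (reduced
# 30 hr window; extend t_end for the full 80 hr run).
name: fig8
model: full
params: set2
simulator: ssa
geometry: line
diffusion: true
n_cells: 100
t_end: 30.0
record_dt: 0.05
seed: 1
analysis_window: [20.0, 30.0]
analysis_species: [cI, AHL]
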