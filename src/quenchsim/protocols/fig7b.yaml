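# Parameter Set 2, single cell, PDE, AHL diffusing away: sustained,
# very regular limit-cycle oscillations.
name: fig7b
model: full
params: set2
simulator: pde
geometry: single_cell
diffusion: true
volume_length: 50.0
perturbation: {species: m_cI, factor: 2.0}
t_end: 40.0
record_dt: 0.02
analysis_species: [m_cI]
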