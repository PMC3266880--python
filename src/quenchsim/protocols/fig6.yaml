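# Parameter Set 2, line of cells, k=5 imprint (above the minimum
# unstable wave number): the imprint grows, saturates, and energy moves
# into higher harmonics late in the run.
name: fig6
model: full
params: set2
simulator: pde
geometry: line
diffusion: true
grid_points: 101
perturbation: {species: m_cI, k: 5, amplitude_frac: 0.5}
t_end: 30.0
record_dt: 0.05
analysis_window: [20.0, 30.0]
analysis_species: [m_cI, AHL]
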