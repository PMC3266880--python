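# Parameter Set 1, line of cells, unstable imprinted wavelength: the
# imprint grows with AHL diffusion.
name: fig4_diffusion
model: full
params: set1
simulator: pde
geometry: line
diffusion: true
grid_points: 101
perturbation: {species: m_cI, k: 4, amplitude_frac: 0.1}
t_end: 40.0
record_dt: 0.1
analysis_window: [4.0, 36.0]
analysis_species: [m_cI, AHL]
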