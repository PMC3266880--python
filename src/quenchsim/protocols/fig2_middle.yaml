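# Toy model with reduced diffusion: D*mu_2 falls below the instability
# threshold and the imprinted inhomogeneity decays slowly.
name: fig2_middle
model: toy
params: toy_fig2
simulator: pde
geometry: line
diffusion: true
D_override: 0.25
grid_points: 101
perturbation: {species: X1, k: 2, amplitude_frac: 0.1}
t_end: 60.0
record_dt: 0.1
analysis_window: [5.0, 50.0]
analysis_species: [X1, X4]
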