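# Toy model, line of cells, large diffusion: the imprinted k=2 wave is
# above the instability threshold and grows.
name: fig2_top
model: toy
params: toy_fig2
simulator: pde
geometry: line
diffusion: true
grid_points: 101
perturbation: {species: X1, k: 2, amplitude_frac: 0.1}
t_end: 60.0
record_dt: 0.1
analysis_window: [5.0, 50.0]
analysis_species: [X1, X4]
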