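# Dimensionless toy quenched-oscillator parameter set (synthetic
# reconstruction chosen to satisfy the Turing conditions: the three-ring
# oscillator block is unstable, the quenched well-mixed system is stable,
# and diffusion of X4 releases modes k >= 2 at D = 1 on the unit domain).
# Instability threshold D*mu ~= 13.41; with D = 1 the k = 2 mode grows and
# with D = 0.25 it decays slowly.
model: toy
description: toy quenched oscillator, pattern-forming regime
p1: 10.0
p2: 2.0
p3: 10.0
p4: 10.0
p5: 8.0
h: 4.0
D: 1.0
L: 1.0
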