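# Wave-pinning (WP) model: population best-fit kinetic parameters from
# temporal fits to latrunculin-treated cells (double-pulse stimulus).
# Diffusion: the spatial WP model was not fit to data; D_v is a conventional
# fast-cytosolic default with D_u = 1 fixing the length scale.
variant: wp
T: 9.78
k0: 0.035
s: 0.12
gamma: 1.31
K: 2.75
n: 2
delta: 2.70
D_u: 1.0
D_v: 10.0
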