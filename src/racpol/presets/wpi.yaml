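# Wave-pinning with inhibitor (WPI): population best-fit kinetic parameters
# from temporal fits, and relative diffusion ratios from spatial fits
# (normalized to active Rac, D_u = 1).
variant: wpi
T: 7.31
k0: 0.028
s: 0.059
gamma: 1.38
K: 2.93
n: 2
delta: 0.721
k1: 0.372
alpha: 6.8e-3
delta_h: 4.0e-3
D_u: 1.0
D_v: 3.37
D_h: 0.14
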