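# WPI-PIP3: light drives PIP3 production and PIP3 activates Rac; kinetic
# parameters carried over from the WPI temporal fits, diffusion ratios from
# the spatial fits.  The PIP3 sub-model constants (k_p, s_p, delta_p, D_p)
# are package defaults chosen so the PIP3 half-life (~69 s) falls between the
# Rac (~1 s) and inhibitor (~173 s) half-lives — the timescale ordering that
# produces rotation reversal; the direct light->Rac gain s is unused (0).
variant: wpi_pip3
T: 7.31
k0: 0.028
s: 0.0
gamma: 1.38
K: 2.93
n: 2
delta: 0.721
k1: 0.372
alpha: 6.8e-3
delta_h: 4.0e-3
k_p: 0.06
s_p: 0.01
delta_p: 0.01
D_u: 1.0
D_v: 6.40
D_h: 0.47
D_p: 0.1
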