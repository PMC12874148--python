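# Qualitative wave-pinning parameter set for spatial/motility work, in the
# classic bistable regime (rates of order 1/s, Hill K=1), rescaled so that
# D_u = 1 fixes the length unit.  The Table-1 temporal-fit WP values (see
# wp.yaml) are monostable for every attainable substrate level and cannot
# pin a wave; use this set when a polarizable WP cell is needed.
# Recommended ring perimeter: L ~ 32 length units.
variant: wp
T: 2.27
k0: 0.067
s: 0.3
gamma: 1.0
K: 1.0
n: 2
delta: 1.0
D_u: 1.0
D_v: 100.0
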