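# racpol

Reaction–diffusion models of Rac GTPase polarity on the edge of a
neutrophil-like cell, with optogenetic stimulation protocols, parameter
fitting, AIC model selection, and a cellular-Potts motility layer.

Directed migration requires polarity that is robust yet steerable. A
mass-conserved wave-pinning circuit — active Rac `u` activating itself
(Hill autocatalysis) while depleting a fast-diffusing inactive pool `v` —
explains stable fronts and simple turning, but not the adaptation and
history dependence seen in optogenetic experiments: Rac responses that
overshoot and decay, smaller second responses to paired light pulses,
and cells that *reverse* their turning when a local light stimulus is
replaced by whole-cell illumination. `racpol` implements the three
nested circuits that dissect those observations:

* **WP** — wave-pinning only:
  `du/dt = (k0 + γu²/(K²+u²) + s·S)·v − δ·u + D_u ∇²u`, `dv/dt = −(…) + D_v ∇²v`
* **WPI** — adds a slow, slowly diffusing local inhibitor produced by Rac:
  `dh/dt = α·u − δ_h·h + D_h ∇²h`, inactivation `(δ + k1·h)·u`
* **WPI-PIP3** — light drives PIP3 (`dp/dt = s_p·S − δ_p·p + D_p ∇²p`),
  and PIP3 activates Rac (`k_p·p` replaces `s·S`)

solved well-mixed (ODE, for immobilized-cell time series) and on a 1D
periodic cell edge (for kymographs and motility). The package is aimed
at modelers studying GTPase polarity circuits and at anyone who wants an
executable, testable version of this model family: every behavioral
claim (adaptation, rate sensing, rotation persistence, rotation
reversal, gradient reorientation) is a function you can run.

## Worked example

Generate a synthetic population of immobilized cells under the 120-s
double-pulse light protocol, fit the inhibitor model to each cell, and
compare circuits by AIC:

```python
from racpol import (PopulationSpec, generate_population, fit_population,
                    select_model, load_preset)

wpi = load_preset("wpi")                      # fitted parameter table
spec = PopulationSpec(n_cells=6, base_params=wpi,
                      heterogeneity_cv=0.0, noise_sd=0.05, seed=7)
traces = generate_population(spec, protocol="double_pulse_120")

pops = {}
for variant in ("wp", "wpi"):
    pop, fits = fit_population(traces, variant, seed=3)
    pops[variant] = pop
    extra = f"delta_h={pop.mean['delta_h']:.5f}  " if variant == "wpi" else ""
    print(f"{variant:>4}  {extra}converged "
          f"{pop.n_successful_cells}/{pop.n_attempted_cells}")

for row in select_model(pops).as_rows():
    print(f"{row['model']:>4}  AIC={row['AIC']:9.1f}  dAIC={row['dAIC']:7.1f}"
          f"  w={row['weight']:.3f}  RSS={row['RSS']:8.2f}")
```

prints (seed 7/3):

```
  wp  converged 6/6
 wpi  delta_h=0.00420  converged 5/6
  wp  AIC=    178.6  dAIC= 1876.6  w=0.000  RSS=  774.93
 wpi  AIC=  -1698.0  dAIC=    0.0  w=1.000  RSS=   14.10
```

The recovered inhibitor decay rate `delta_h ≈ 0.0042 /s` sits within the
fitted table's 95% interval around 0.0040 /s (half-life ≈ 173 s), and
AIC decisively prefers the inhibitor circuit on data that contain
adaptation — the WP model cannot produce the overshoot or the smaller
second peak, no matter its parameters.

Run the command-line interpretation report (`racpol interpret`) to see
the derived quantities: inhibitor half-life 173 s versus ~1 s for active
Rac, basal activation ≈ 2.7% of the autocatalytic rate, and an inferred
inhibitor molecular weight ≈ 9.6× Rac from the fitted diffusion ratio.

Motility phenotypes are one call each, e.g. the local-to-global
rotation-reversal experiment:

```python
from racpol import front_rotation_label
from racpol.cpm_motility import run_local_to_global

res = run_local_to_global("wpi_pip3", seed=3)
print(front_rotation_label(res.track, t_start=res.switch_time + 30))
# -> "CW"  (the rotation reverses after the global switch)
```

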