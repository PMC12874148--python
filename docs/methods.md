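# Methods

`racpol` implements three nested reaction–diffusion circuits for Rac
GTPase polarity on the edge of a neutrophil-like cell, the optogenetic
stimulation protocols used to interrogate them, parameter estimation with
model selection, and a cellular-Potts motility layer that turns edge Rac
into cell movement. This note records the models, the numerical choices,
the calibrations that were genuinely open, and what the synthetic-data
tests do and do not establish.

## Models

All three circuits share a conserved Rac pool: active Rac `u` (membrane,
slow diffusing) and inactive Rac `v` (cytosolic, fast diffusing) with
`u + v` conserved. Activation is `(k0 + gamma*u^n/(K^n + u^n) + drive) * v`
with Hill coefficient `n = 2` (fixed); inactivation is first order.

* **WP** (wave-pinning): drive `= s*S(theta, t)`; inactivation `delta*u`.
  Bistable in the right parameter range: an activation front travels and
  stalls by depleting `v`, leaving a stable polar pattern.
* **WPI**: adds a local inhibitor `h` produced by active Rac
  (`dh/dt = alpha*u - delta_h*h`) that raises inactivation to
  `delta + k1*h`. The slow negative feedback produces adaptation
  (overshoot, undershoot, smaller second response), rate sensing, and
  traveling Rac waves (cell rotation).
* **WPI-PIP3**: light drives PIP3 (`dp/dt = s_p*S - delta_p*p`) and PIP3
  drives Rac (`k_p*p` in place of `s*S`); the light no longer acts on Rac
  directly. The intermediate adds a memory field whose spatial residue
  steers reversal behavior.

Units: seconds; concentrations in arbitrary units (AU). Outputs are
reported as fold change of `u` over its unstimulated rest level `u*`
(the lowest positive root of the well-mixed kinetics; bistable parameter
sets also have a high root, which is never used as a baseline). Diffusion
coefficients are relative to active Rac (`D_u = 1`), which also fixes the
length unit.

## Parameter sets

Four presets ship with the package:

* `wp`, `wpi`: population best-fit kinetic values from temporal fits to
  immobilized (latrunculin-treated) cells, plus the relative diffusion
  ratios from spatial fits (`wpi` only: D_v = 3.37, D_h = 0.14).
* `wpi_pip3`: WPI kinetics with the PIP3 sub-model constants, which are
  package defaults, not fitted values: `s_p = delta_p = 0.01 /s`
  (PIP3 plateau 1 AU, half-life ~69 s — between the Rac (~1 s) and
  inhibitor (~173 s) half-lives, the ordering required for reversal),
  `k_p = 0.06 /(AU s)` (matching the WPI direct light gain at PIP3
  plateau), `D_p = 0.1`, `D_v = 6.40`, `D_h = 0.47`.
* `wp_spatial`: a qualitative bistable wave-pinning set (rates of order
  1/s, K = 1, T = 2.27, D_v = 100, recommended ring L ~ 32). This preset
  exists because the WP *temporal-fit* values are monostable for every
  attainable substrate level `v <= T` (max activation rate
  `k0 + gamma = 1.35 /s` is far below `delta = 2.70 /s`): they can fit
  well-mixed traces but cannot pin a wave or polarize a cell, so all
  spatial and motility WP experiments use `wp_spatial`.

### Identifiability

Fold-normalized readouts leave the WPI model with two exact gauge
freedoms. First, the inhibitor enters only through `k1*h` and `h` is
linear in `alpha`, so `(k1, alpha) -> (c*k1, alpha/c)` changes nothing.
Second, the concentration scale itself is free: `(T, K, k1) ->
(c*T, c*K, k1/c)` rescales `u, v, h` by `c` and leaves the fold-change
output untouched. The identifiable quantities are the rates
`k0, s, gamma, delta, delta_h` and the combinations `T/K` and
`k1*alpha*K`; recovery tests score exactly these. Absolute values of
`T`, `K`, `k1`, `alpha` are meaningful only under a scale convention.

## Spatial solver

1D periodic ring of `n_bins` angular bins (default 100), compass angles
(0 = north, counterclockwise positive). Strang splitting with
Crank–Nicolson diffusion applied spectrally (the periodic Laplacian is
circulant, so CN is an exact per-mode rational multiplier) and classical
RK4 for the reactions; `dt = 0.05 s` default. Both sub-steps conserve
total Rac to round-off. Halving `dt` moves the double-pulse spatial-mean
trace by < 1e-3 in relative L2 (pointwise comparison at the near-vertical
flanks of excitable spikes measures only phase error and is not used).

**Ring perimeter.** Only diffusion *ratios* are reported by the fits, so
the physical perimeter L is a configuration choice. The default L = 80
(length units of `sqrt(D_u s)`) was chosen once for the WPI circuit:
it supports a single Rac zone and a sustained traveling wave (rotation at
~0.5–2 deg/s). Rings above ~125 admit multiple simultaneous zones under
global illumination (front tracking becomes meaningless), and rings below
~60 suppress the chased rotation. WP spatial runs use L = 32 with the
`wp_spatial` preset (scaled from its classic formulation).

## Stimuli

A protocol is a sum of components: spatial profile (uniform, or Gaussian
patch with FWHM default 30 deg, wrapped around the ring so the opposite
side sees a strictly positive tail) x temporal profile (step, double
pulse, ramp, constant) x dimensionless amplitude. The biochemical gain
stays in `s` (or `s_p`), so the temporal-fit amplitude convention is
`S in {0, 1}`. Spatial experiments are not bound by that convention (the
spatial light intensity was never fit); the competing-stimulus experiment
below uses amplitude 3.

## Behavioral experiments and their calibrations

These are the places where the spec of the experiment was genuinely open
and the package fixes a convention. All constants are exposed as function
arguments.

**Step versus ramp (well-mixed rate sensing).** The WPI circuit is
excitable: *any* supra-threshold ramp eventually fires one spike, no
matter how slow, because the fast Rac subsystem crosses its fold long
before the inhibitor can track it. The discriminating regime is moderate
amplitude: at `amplitude = 0.1` an abrupt step fires a full spike
(overshoot ratio ~6) while a 600-s ramp to the same final level is
tracked quasi-statically (overshoot < 0.1). `experiment_step_vs_ramp`
encodes these defaults. At amplitude 1 both inputs fire, differing only
in latency.

**Competing stimuli on the ring.** With the fitted WPI values, a zone
held by constant light is destabilized by its own inhibitor on a
150–250 s horizon (it hops to the antipode and back), and an abruptly
switched-on hold flings a transient wave around the ring. The step/ramp
contrast is therefore read out in a finite window: the hold (amplitude 3,
FWHM 45 deg, at -90 deg) is ramped in over 150 s and left to settle; the
competitor at +90 deg arrives at t = 400 s either as a step or as a ramp
reaching full strength over 900 s; the run ends 75 s later. By then the
step has relocated the Rac peak to +90 deg (it does so within ~10 s)
while the ramp — still far below the inhibitor timescale — has not moved
it (first departure ~105 s after onset). On longer horizons the zone hops
under every stimulation mode; the window, not the asymptotics, carries
the rate-sensing signal.

**Local-to-global rotation experiment.** A Gaussian patch chases the Rac
front at a fixed angular lead, driving rotation; after enough rotation
the light switches to uniform. Three calibrations:

* *Chase lead*: 45 deg for WP/WPI, 90 deg for WPI-PIP3. The experimental
  light always acts through PI3K/PIP3; the WP/WPI models collapse that
  intermediate into a direct Rac term, so their patch sits closer ahead
  to give a comparable effective activation offset. (At 90 deg the
  direct-drive chase runs away to nonphysical rotation speeds >8 deg/s.)
* *Switch trigger*: the hand-over to global light fires when the front
  has accumulated a set rotation (400 deg for WPI, 300 deg for
  WPI-PIP3), not at a clock time. The post-switch direction is decided
  by the geometry of the inhibitor and PIP3 trails at the switch moment;
  accumulated rotation, not elapsed time, is the variable that aligns
  that geometry across cells with heterogeneous rotation speeds. WPI
  continuation needs a mature inhibitor trail (late switch); WPI-PIP3
  reversal needs the switch to occur while rotation is still slow
  (<~1 deg/s), before the PIP3 bump is smeared behind the front.
* The pre-stimulus free-migration phase is reduced to 10 s:
  an unstimulated polarized cell of the inhibitor circuits drifts into a
  traveling wave of arbitrary direction, so a long preamble only
  randomizes the phase the protocol then has to overcome.

With per-cell lognormal parameter heterogeneity (CV 0.1) the cohort
outcome is a majority, not a certainty — a fraction of WPI-PIP3 cells
fail to reverse, as in the experimental data.

**Gradient reversal.** Attractant concentration is linear in the
northward coordinate (range 0–1 across the lattice); each edge bin
converts the concentration at its boundary pixel into local activation
with gain 0.15 (higher gains flood the ring with activation and destroy
WP polarity; much lower gains leave no measurable bias). Timeline:
gradient up from t = 0, uniform at t = 80 s, reversed from t = 120 s.
Reorientation time is the first confirmed positive-to-negative crossing
of the 20-s-smoothed vertical velocity after the reversal; a crossing
counts only if the velocity then reaches -0.02 px/s within 60 s
(unconfirmed zero grazes are lattice noise). Runs use the 200x200
lattice so the non-reorienting WP cell does not reach the boundary
within the run.

## Cellular-Potts layer

Single cell, square lattice (default 200x200, target area 500 px^2),
Metropolis copy attempts with energy
`lambda_A (A - A0)^2 + lambda_P (P - P0)^2 + J*P` (P = cell–medium
4-neighbor links) and a work term `-lambda_Rac (u(theta) - mean u)` for
extension (sign reversed for retraction) at the attempt pixel's polar
angle about the centroid. Both the cell and the medium must remain
locally simply connected at the flipped pixel (no fragmentation, no
holes); one MCS = one attempt per lattice site; 1 MCS = 1 s by default.
All lattice constants are package choices (no published values exist for
this system) and are config-exposed. The ring keeps a fixed number of
angle bins while the perimeter fluctuates; bin values are densities, not
remapped mass.

The chasing patch in front-relative mode re-aims every 5 s at the
circular-mean direction of the `u` distribution. Cohort and unit-test
runs use a 100x100 lattice with A0 = 300 to keep the suite fast; the
phenotype labels are unchanged at 200x200.

## Synthetic data

The generator emulates the structure of per-cell optogenetic recordings:
PIP3 forcing with first-order rise under light and exponential dark decay
(exact piecewise solution), lognormal cell-to-cell amplitude spread
(sigma 0.4 — the data's PIP3 responses "vary strongly" but no number is
printed), lognormal kinetic-parameter heterogeneity (CV 0.2 default on
rates, 0 on `n`), and multiplicative lognormal measurement noise
(sigma 0.05 — fluorescence-ratio data are positive and
scale-dependent). Sampling every 5 s for 480 s. Ground-truth parameters
are stored with every cell.

What passing recovery tests show: the fitting pipeline is unbiased at
the generating model and its noise structure. What they do not show:
robustness to real-data pathologies the generator omits — photobleaching
trends, segmentation artifacts, non-stationary baselines, model
misspecification of the PIP3 channel.

## Fitting

Differential evolution (best1bin-style, population multiplier 6,
maxiter 500, tolerance 0.02 on the relative population-energy spread,
L-BFGS-B polish) minimizes the RSS between the model's fold-change output
and the cell's Rac trace, with the cell's own PIP3 trace as the
activation input. The objective integrates a compiled fixed-step RK4
(dt 0.1 s) copy of the kinetics; a test pins it against the adaptive
LSODA reference (rtol 1e-6, atol 1e-9) at 5e-4 relative. Default bounds
span a 10x range around the preset values. A fit converges when the
optimizer meets its tolerance, the fitted baseline stays within 10% of 1,
and the trace actually contains a stimulus response.

Population aggregates use converged cells only; 95% intervals are
`1.96*sd/sqrt(n)` of the per-cell best fits. AIC is
`n ln(RSS/n) + 2k` on pooled residuals (n = all residual points of all
converged cells; the original report's sample-count convention is not
reconstructible), with Akaike weights `exp(-delta/2)` normalized.

Spatial fitting holds kinetics fixed and estimates `(D_v, D_h)` from
averaged angle-resolved profiles; `D_v > D_u` is enforced through its
lower bound, while the `D_h` range extends well below `D_u`.

## Known limitations

* Behavioral outcomes of the inhibitor circuits (continuation versus
  reversal) are genuinely phase-sensitive; the rotation-triggered switch
  makes cohort majorities reproducible but individual cells near the
  trigger boundary can flip. This mirrors the experimentally observed
  non-reversing minority but is a property of this parameter regime, not
  a validated single-cell prediction.
* After a gradient reversal the WPI-PIP3 cell does **not** reorient
  faster than WPI in this formulation (medians over 20 seeds: 282 s vs
  264 s, overlapping distributions). The gradient reaches Rac only
  through the PIP3 equation, whose ~100 s timescale delays the cell's
  perception of the reversed field; shortening that timescale would
  remove the delay but destroys the local-to-global rotation reversal,
  which we prioritized. Both inhibitor circuits do reorient while the
  pure wave-pinning cell never does.
* The ring geometry is fixed; no membrane tension, no Rho/Cdc42, no
  deforming-domain PDEs, no multi-cell interactions.
* The temporal-fit WP preset cannot polarize; WP spatial claims rest on
  the qualitative `wp_spatial` regime.
* Reported times (reorientation medians, hop horizons) depend on the
  lattice and coupling constants above; only orderings and phenotype
  labels are treated as reproducible.
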