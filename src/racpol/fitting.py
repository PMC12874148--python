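"""Parameter estimation by differential evolution and AIC model selection.

Temporal fitting drives the well-mixed WP or WPI model with each cell's own
PIP3 trace as the activation input and minimizes the residual sum of
squares against that cell's Rac fold-change readout.  Per-cell best fits
aggregate into population means with 95% intervals.  Spatial fitting holds
the kinetic parameters fixed and estimates relative diffusion ratios from
angle-resolved Rac profiles.  Model comparison uses AIC on pooled
residuals with Akaike weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import differential_evolution

from ._fastode import rss_forced
from .core_models import ModelParams, Variant, load_preset
from .rd_solver import EdgeGrid, simulate_edge
from .synthetic_data import CellTrace

#: ordering of the temporal-fit parameter vector (WP uses the first six)
WP_FIT_FIELDS = ("T", "k0", "s", "gamma", "K", "delta")
WPI_FIT_FIELDS = WP_FIT_FIELDS + ("k1", "alpha", "delta_h")

#: reduced differential-evolution budget: population multiplier, generations
DEFAULT_DE_POPSIZE = 6
DEFAULT_DE_MAXITER = 500
DEFAULT_DE_TOL = 0.02  # relative population-energy spread
DEFAULT_DE_ATOL = 1e-6  # absolute spread floor (noiseless objectives -> 0)
FAST_DT = 0.1  # s, fixed step of the compiled objective integrator
BOUNDS_SPAN = math.sqrt(10.0)  # default bounds: value / span .. value * span


class FitError(RuntimeError):
    pass


@dataclass
class FitResult:
    """Best fit of one model variant to one cell."""

    cell_id: str
    variant: Variant
    best_params: ModelParams
    rss: float
    n_obs: int
    converged: bool
    seed: int
    message: str = ""


@dataclass
class PopulationFit:
    """Across-cell aggregate of per-cell best fits."""

    variant: Variant
    mean: Dict[str, float]
    ci95_half_width: Dict[str, float]
    n_successful_cells: int
    n_attempted_cells: int
    total_rss: float
    total_n_obs: int


@dataclass
class ModelSelection:
    """AIC comparison table across model variants."""

    models: List[str]
    aic: List[float]
    delta_aic: List[float]
    weight: List[float]
    rss: List[float]
    n_samples: int
    k_params: List[int]

    def as_rows(self) -> List[dict]:
        return [dict(model=m, AIC=a, dAIC=d, weight=w, RSS=r,
                     n=self.n_samples, k=k)
                for m, a, d, w, r, k in zip(
                    self.models, self.aic, self.delta_aic, self.weight,
                    self.rss, self.k_params)]


def fit_fields(variant: "Variant | str") -> Tuple[str, ...]:
    variant = Variant.coerce(variant)
    if variant is Variant.WP:
        return WP_FIT_FIELDS
    if variant is Variant.WPI:
        return WPI_FIT_FIELDS
    raise FitError("temporal fitting supports the WP and WPI variants; the "
                   "WPI-PIP3 stimulus does not act directly on Rac")


def default_bounds(variant: "Variant | str",
                   center: Optional[ModelParams] = None,
                   span: float = BOUNDS_SPAN) -> Dict[str, Tuple[float, float]]:
    """Per-parameter box bounds spanning a 10x range around a center
    parameter set (the packaged preset by default)."""
    variant = Variant.coerce(variant)
    center = center or load_preset(variant)
    return {name: (getattr(center, name) / span, getattr(center, name) * span)
            for name in fit_fields(variant)}


def _theta_from_params(params: ModelParams) -> np.ndarray:
    vals = [getattr(params, f) for f in WPI_FIT_FIELDS]
    return np.array([v if v is not None else 0.0 for v in vals], dtype=float)


def _params_from_theta(theta: np.ndarray, variant: Variant,
                       template: ModelParams) -> ModelParams:
    updates = {f: float(x) for f, x in zip(fit_fields(variant), theta)}
    return template.with_updates(**updates)


def _check_trace(trace: CellTrace) -> None:
    times = np.asarray(trace.times, dtype=float)
    if len(times) < 4 or np.any(np.diff(times) <= 0):
        raise FitError("trace needs strictly increasing times")
    steps = np.diff(times)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise FitError("temporal fitting expects uniform sampling")
    if np.any(np.asarray(trace.pip3) < 0) or np.any(np.asarray(trace.rac) < 0):
        raise FitError("negative values in trace")


def fit_cell_temporal(trace: CellTrace, variant: "Variant | str",
                      bounds: Optional[Dict[str, Tuple[float, float]]] = None,
                      seed: int = 0,
                      popsize: int = DEFAULT_DE_POPSIZE,
                      maxiter: int = DEFAULT_DE_MAXITER,
                      tol: float = DEFAULT_DE_TOL,
                      atol: float = DEFAULT_DE_ATOL,
                      polish: bool = True) -> FitResult:
    """Differential-evolution fit of one cell's Rac trace.

    The cell's PIP3 trace is the activation input (it replaces the on/off
    light timing in the ``s*S`` term).  The result is flagged unconverged
    when the optimizer hits its iteration cap without meeting ``tol``, when
    the fitted trajectory's pre-stimulus baseline deviates from 1 by more
    than 10%, or when the trace carries no stimulus response at all.
    """
    variant = Variant.coerce(variant)
    fields = fit_fields(variant)
    _check_trace(trace)
    bounds = bounds or default_bounds(variant)
    lohi = [bounds[f] for f in fields]
    times = np.asarray(trace.times, dtype=float)
    forcing = np.asarray(trace.pip3, dtype=float)
    rac = np.asarray(trace.rac, dtype=float)
    has_h = variant is Variant.WPI
    template = load_preset(variant)

    def objective(x):
        theta = np.zeros(9)
        theta[: len(x)] = x
        return rss_forced(theta, has_h, times, forcing, rac, FAST_DT)

    result = differential_evolution(
        objective, lohi, seed=seed, popsize=popsize, maxiter=maxiter,
        tol=tol, atol=atol, polish=polish, init="latinhypercube",
        updating="immediate")
    theta = np.zeros(9)
    theta[: len(result.x)] = result.x
    best = _params_from_theta(result.x, variant, template)
    # baseline sanity: simulated pre-stimulus segment must sit at 1
    from ._fastode import integrate_forced
    pred = integrate_forced(theta, has_h, times, forcing, FAST_DT)
    pre = forcing <= 1e-12
    i_on = int(np.argmax(~pre)) if np.any(~pre) else len(times)
    baseline_ok = i_on == 0 or np.all(np.abs(pred[:i_on] - 1.0) <= 0.1)
    responsive = float(np.max(rac) - np.min(rac)) > 0.05
    converged = bool(result.success) and baseline_ok and responsive
    msg = result.message if not result.success else (
        "" if responsive else "no stimulus response in trace")
    return FitResult(cell_id=trace.cell_id, variant=variant, best_params=best,
                     rss=float(result.fun), n_obs=len(rac),
                     converged=converged, seed=seed, message=str(msg))


def fit_population(traces: Sequence[CellTrace], variant: "Variant | str",
                   bounds: Optional[Dict[str, Tuple[float, float]]] = None,
                   seed: int = 0,
                   **de_kwargs) -> Tuple[PopulationFit, List[FitResult]]:
    """Fit every cell independently and aggregate the converged fits.

    The 95% interval half-width is 1.96 * sd / sqrt(n) of the per-cell
    best-fit distribution.  Each cell gets a distinct but seed-derived
    optimizer seed, so the whole run is reproducible.
    """
    variant = Variant.coerce(variant)
    if len(traces) < 2:
        raise FitError("population fitting needs at least 2 traces")
    fits = [fit_cell_temporal(tr, variant, bounds=bounds,
                              seed=seed + 1000 * i, **de_kwargs)
            for i, tr in enumerate(traces)]
    good = [f for f in fits if f.converged]
    if not good:
        raise FitError("no cell converged; nothing to aggregate")
    fields = fit_fields(variant)
    mean, half = {}, {}
    for f in fields:
        vals = np.array([getattr(g.best_params, f) for g in good])
        mean[f] = float(vals.mean())
        half[f] = float(1.96 * vals.std(ddof=1) / math.sqrt(len(vals))) \
            if len(vals) > 1 else 0.0
    pop = PopulationFit(
        variant=variant, mean=mean, ci95_half_width=half,
        n_successful_cells=len(good), n_attempted_cells=len(fits),
        total_rss=float(sum(g.rss for g in good)),
        total_n_obs=int(sum(g.n_obs for g in good)))
    return pop, fits


# ---------------------------------------------------------------------------
# spatial diffusion fitting
# ---------------------------------------------------------------------------

def fit_spatial_diffusion(profiles: dict, variant: "Variant | str",
                          kinetic_params: Optional[ModelParams] = None,
                          seed: int = 0,
                          bounds_dv: Tuple[float, float] = (1.0, 20.0),
                          bounds_dh: Tuple[float, float] = (0.01, 5.0),
                          popsize: int = 6, maxiter: int = 8,
                          grid: Optional[EdgeGrid] = None,
                          dt: float = 0.1) -> dict:
    """Estimate relative diffusion ratios (D_v, D_h; D_u = 1) from averaged
    spatial Rac profiles, holding the temporal-fit kinetics fixed.

    ``profiles`` maps protocol name -> dict with ``times``, ``theta`` and
    ``mean`` (snapshots x bins, AU), as produced by
    :func:`racpol.synthetic_data.generate_spatial_profiles`.  D_v > D_u is
    enforced through its lower bound (fast cytosolic inactive Rac); the
    D_h range deliberately extends below D_u (slow local inhibitor).
    """
    variant = Variant.coerce(variant)
    if variant is Variant.WP:
        raise FitError("spatial ratio fitting is defined for the "
                       "inhibitor-carrying variants")
    params = kinetic_params or load_preset(variant)
    grid = grid or EdgeGrid()
    # identifiability guard: a totally flat target cannot constrain ratios
    flat = all(np.allclose(d["mean"], d["mean"].mean()) for d in profiles.values())
    if flat:
        return {"D_v": None, "D_h": None, "identifiable": False,
                "rss": None, "message": "uniform profiles: unidentifiable"}

    from .stimulus import get_preset

    protos = {name: get_preset(name) for name in profiles}

    def objective(x):
        dv, dh = x
        prm = params.with_updates(D_v=float(dv), D_h=float(dh))
        err = 0.0
        for name, data in profiles.items():
            t_end = float(np.max(data["times"]))
            run = simulate_edge(prm, grid=grid, protocol=protos[name],
                                t_end=t_end, dt_out=1.0, dt=dt)
            for ts, target in zip(data["times"], data["mean"]):
                sim_prof = run.u.values[int(round(ts))]
                err += float(np.sum((sim_prof - target) ** 2))
        return err

    result = differential_evolution(
        objective, [bounds_dv, bounds_dh], seed=seed, popsize=popsize,
        maxiter=maxiter, tol=1e-6, polish=True, updating="immediate")
    return {"D_v": float(result.x[0]), "D_h": float(result.x[1]),
            "identifiable": True, "rss": float(result.fun),
            "message": str(result.message)}


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def compute_aic(rss: float, n_obs: int, k_params: int) -> float:
    """AIC = n * ln(RSS / n) + 2k (least-squares form); lower is better."""
    if rss <= 0 or n_obs <= 0 or k_params < 1:
        raise ValueError("need rss > 0, n_obs > 0, k_params >= 1")
    return n_obs * math.log(rss / n_obs) + 2 * k_params


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """w_i = exp(-d_i/2) / sum_j exp(-d_j/2) with d_i = AIC_i - min AIC."""
    aics = np.asarray(aics, dtype=float)
    d = aics - aics.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


def select_model(pop_fits: Dict[str, PopulationFit]) -> ModelSelection:
    """AIC table across fitted variants.

    The AIC sample count is the number of residual points entering the
    pooled RSS (all converged cells x all time points).
    """
    models = list(pop_fits)
    rss = [pop_fits[m].total_rss for m in models]
    ks = [len(fit_fields(pop_fits[m].variant)) for m in models]
    ns = [pop_fits[m].total_n_obs for m in models]
    aics = [compute_aic(r, n, k) for r, n, k in zip(rss, ns, ks)]
    d = [a - min(aics) for a in aics]
    w = akaike_weights(aics)
    return ModelSelection(models=models, aic=aics, delta_aic=d,
                          weight=[float(x) for x in w], rss=rss,
                          n_samples=max(ns), k_params=ks)
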