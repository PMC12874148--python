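"""Reaction kinetics of the three nested Rac polarity circuits.

Three model variants describe active Rac (u), inactive Rac (v), a putative
slow Rac inhibitor (h) and the upstream phosphoinositide PIP3 (p):

* **WP** (wave-pinning): mass-conserved activator/substrate pair with
  Hill-type Rac autocatalysis; light adds an extra activation rate ``s*S``.
* **WPI**: WP plus an inhibitor produced in proportion to active Rac and
  decaying with first-order kinetics; the inhibitor raises Rac inactivation.
* **WPI-PIP3**: WPI in which light no longer acts on Rac directly but drives
  PIP3 production, and PIP3 in turn promotes Rac activation (``k_p*p``).

All rates are per second; concentrations in arbitrary units (AU).  Model
output is reported as fold change of active Rac over its unstimulated rest
level, matching how fluorescence-ratio data are normalized.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import brentq


class Variant(str, enum.Enum):
    """Model variant identifier."""

    WP = "wp"
    WPI = "wpi"
    WPI_PIP3 = "wpi_pip3"

    @classmethod
    def coerce(cls, value: "Variant | str") -> "Variant":
        if isinstance(value, Variant):
            return value
        return cls(str(value).lower().replace("-", "_"))


#: fields that only exist for the inhibitor-carrying variants
_WPI_ONLY = ("k1", "alpha", "delta_h", "D_h")
#: fields that only exist for the PIP3-carrying variant
_PIP3_ONLY = ("k_p", "s_p", "delta_p", "D_p")


class ModelConfigError(ValueError):
    """Raised when parameters are inconsistent with the chosen variant."""


@dataclass(frozen=True)
class ModelParams:
    """Kinetic and diffusion parameters for one model variant.

    Diffusion coefficients are relative to active Rac (``D_u = 1`` fixes the
    length scale).  Fields irrelevant to a variant must be ``None``.
    """

    variant: Variant
    T: float  # total Rac density (AU)
    k0: float  # basal activation rate (1/s)
    s: float  # stimulus-induced activation rate (1/s)
    gamma: float  # autocatalytic activation rate (1/s)
    K: float  # Hill half-max (AU)
    delta: float  # basal inactivation rate (1/s)
    n: int = 2  # Hill coefficient
    k1: Optional[float] = None  # inhibitor-induced inactivation (1/(AU*s))
    alpha: Optional[float] = None  # inhibitor production by Rac (1/s)
    delta_h: Optional[float] = None  # inhibitor decay (1/s)
    k_p: Optional[float] = None  # PIP3-induced activation (1/(AU*s))
    s_p: Optional[float] = None  # light-driven PIP3 production (AU/s)
    delta_p: Optional[float] = None  # PIP3 decay (1/s)
    D_u: float = 1.0
    D_v: float = field(default=10.0)
    D_h: Optional[float] = None
    D_p: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", Variant.coerce(self.variant))
        if self.T <= 0:
            raise ModelConfigError("total Rac T must be positive")
        if self.K <= 0:
            raise ModelConfigError("Hill half-max K must be positive")
        if self.n < 1:
            raise ModelConfigError("Hill coefficient n must be >= 1")
        for name in ("k0", "s", "gamma", "delta", "D_u", "D_v"):
            if getattr(self, name) < 0:
                raise ModelConfigError(f"rate {name} must be non-negative")
        needs_h = self.variant in (Variant.WPI, Variant.WPI_PIP3)
        needs_p = self.variant is Variant.WPI_PIP3
        for name in _WPI_ONLY:
            val = getattr(self, name)
            if needs_h and val is None:
                raise ModelConfigError(f"{self.variant.value} requires {name}")
            if not needs_h and val is not None:
                raise ModelConfigError(
                    f"{name} is not a parameter of the {self.variant.value} model"
                )
            if val is not None and val < 0:
                raise ModelConfigError(f"rate {name} must be non-negative")
        for name in _PIP3_ONLY:
            val = getattr(self, name)
            if needs_p and val is None:
                raise ModelConfigError(f"{self.variant.value} requires {name}")
            if not needs_p and val is not None:
                raise ModelConfigError(
                    f"{name} is not a parameter of the {self.variant.value} model"
                )
            if val is not None and val < 0:
                raise ModelConfigError(f"rate {name} must be non-negative")

    # -- convenience -------------------------------------------------------
    @property
    def has_inhibitor(self) -> bool:
        return self.variant in (Variant.WPI, Variant.WPI_PIP3)

    @property
    def has_pip3(self) -> bool:
        return self.variant is Variant.WPI_PIP3

    def with_updates(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        out = {"variant": self.variant.value}
        for name in (
            "T", "k0", "s", "gamma", "K", "n", "delta", "k1", "alpha",
            "delta_h", "k_p", "s_p", "delta_p", "D_u", "D_v", "D_h", "D_p",
        ):
            val = getattr(self, name)
            if val is not None:
                out[name] = val
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        return cls(**data)


def load_preset(name: "Variant | str") -> ModelParams:
    """Load a packaged parameter preset: ``wp``, ``wpi``, ``wpi_pip3``
    (population best-fit tables) or ``wp_spatial`` (bistable qualitative
    wave-pinning set for spatial/motility work)."""
    key = name.value if isinstance(name, Variant) else \
        str(name).lower().replace("-", "_")
    ref = resources.files("racpol").joinpath(f"presets/{key}.yaml")
    if not ref.is_file():
        raise KeyError(f"no packaged preset named {key!r}")
    with ref.open("r") as fh:
        data = yaml.safe_load(fh)
    return ModelParams.from_dict(data)


@dataclass
class WellMixedState:
    """Point (well-mixed) state of the reaction system."""

    u: float
    v: float
    h: float = 0.0
    p: float = 0.0
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v, self.h, self.p], dtype=float)


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def hill_activation(u, params: ModelParams):
    """Saturating autocatalytic Rac activation rate gamma*u^n/(K^n + u^n).

    Accepts scalars or arrays; ``u = K`` gives exactly ``gamma / 2``.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0):
        raise ValueError("active Rac u must be non-negative")
    un = u_arr ** params.n
    out = params.gamma * un / (params.K ** params.n + un)
    return out if out.ndim else float(out)


def activation_rate(u, p, S, params: ModelParams):
    """Total per-capita Rac activation rate (applied to the inactive pool)."""
    rate = params.k0 + hill_activation(u, params)
    if params.has_pip3:
        rate = rate + params.k_p * np.asarray(p, dtype=float)
    else:
        rate = rate + params.s * np.asarray(S, dtype=float)
    return rate


def inactivation_rate(h, params: ModelParams):
    """Per-capita Rac inactivation rate, raised by the inhibitor if present."""
    if params.has_inhibitor:
        return params.delta + params.k1 * np.asarray(h, dtype=float)
    return params.delta


def reaction_terms(state: WellMixedState, S: float, params: ModelParams):
    """Reaction rates (du/dt, dv/dt, dh/dt, dp/dt) at one state.

    Active and inactive Rac have exactly opposite kinetics so the total Rac
    pool is conserved by construction.
    """
    if min(state.u, state.v, state.h, state.p) < 0:
        raise ValueError("state concentrations must be non-negative")
    if S < 0:
        raise ValueError("stimulus S must be non-negative")
    du = activation_rate(state.u, state.p, S, params) * state.v \
        - inactivation_rate(state.h, params) * state.u
    dh = params.alpha * state.u - params.delta_h * state.h \
        if params.has_inhibitor else 0.0
    dp = params.s_p * S - params.delta_p * state.p if params.has_pip3 else 0.0
    return float(du), float(-du), float(dh), float(dp)


# ---------------------------------------------------------------------------
# rest state and normalization
# ---------------------------------------------------------------------------

class RestStateError(RuntimeError):
    """No admissible unstimulated rest state exists for these parameters."""


def _rest_residual(u: float, params: ModelParams) -> float:
    """g(u): net du/dt at S=0 with v = T - u and h, p at their slaved values."""
    h = params.alpha * u / params.delta_h if params.has_inhibitor else 0.0
    act = params.k0 + float(hill_activation(u, params))
    return act * (params.T - u) - (params.delta + (params.k1 * h if params.has_inhibitor else 0.0)) * u


def compute_rest_state(params: ModelParams, tol: float = 1e-12) -> WellMixedState:
    """Unstimulated rest state; the lowest positive root of the well-mixed
    kinetics (low-activity branch when the system is bistable).

    The inhibitor rests at ``alpha*u/delta_h`` and PIP3 at zero.
    """
    if params.has_inhibitor and params.delta_h == 0:
        raise RestStateError("delta_h = 0 gives no inhibitor rest level")
    # g(0) = k0*T > 0 (or 0 if k0 == 0), g(T) = -decay*T < 0: scan for the
    # first sign change to pick the lowest positive root.
    n_scan = 4096
    us = np.linspace(0.0, params.T, n_scan + 1)
    gs = np.array([_rest_residual(float(u), params) for u in us])
    idx = np.nonzero((gs[:-1] > 0) & (gs[1:] <= 0))[0]
    if len(idx) == 0:
        raise RestStateError("no positive rest state found (degenerate params)")
    lo, hi = float(us[idx[0]]), float(us[idx[0] + 1])
    u_star = brentq(_rest_residual, lo, hi, args=(params,), xtol=tol, rtol=8.9e-16)
    h_star = params.alpha * u_star / params.delta_h if params.has_inhibitor else 0.0
    return WellMixedState(u=float(u_star), v=float(params.T - u_star),
                          h=float(h_star), p=0.0, t=0.0)


def normalize_to_baseline(u_values, params: ModelParams,
                          rest: Optional[WellMixedState] = None):
    """Convert active-Rac values to fold change over the unstimulated rest
    level (pre-stimulus segment maps to 1.0)."""
    rest = rest or compute_rest_state(params)
    if rest.u <= 0:
        raise RestStateError("degenerate baseline: rest-state u* is zero")
    return np.asarray(u_values, dtype=float) / rest.u


# ---------------------------------------------------------------------------
# well-mixed integration
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Sampled well-mixed trajectory in fold-change units."""

    times: np.ndarray
    u: np.ndarray  # fold change of active Rac
    v: np.ndarray  # AU
    h: np.ndarray  # AU
    p: np.ndarray  # AU
    u_rest: float  # AU baseline used for normalization


def _forcing_interpolator(times: Sequence[float], values: Sequence[float],
                          t_end: float):
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if np.any(y < 0):
        raise ValueError("forcing trace must be non-negative")
    if t[-1] < t_end:
        raise ValueError(
            f"forcing trace ends at {t[-1]:g} s, before t_end = {t_end:g} s")

    def interp(tq: float) -> float:
        return float(max(np.interp(tq, t, y), 0.0))

    return interp


def integrate_well_mixed(
    params: ModelParams,
    protocol=None,
    t_end: float = 480.0,
    dt_out: float = 5.0,
    pip3_forcing=None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the well-mixed (diffusion-free) model from its rest state.

    ``protocol`` supplies the light input ``S(t)`` (evaluated at angle 0; the
    well-mixed reduction only makes sense for spatially uniform stimuli).
    If ``pip3_forcing`` is given (an object with ``times`` and ``pip3``
    attributes, e.g. a :class:`~racpol.synthetic_data.CellTrace`), the
    measured PIP3 trace — linearly interpolated, clipped at zero — replaces
    ``S`` in the activation term ``s*S``; this is only meaningful for the WP
    and WPI variants, whose stimulus acts directly on Rac.

    Integration uses an adaptive stiff-capable method (LSODA), restarted at
    stimulus discontinuities so steps never straddle a switch.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if pip3_forcing is not None and params.has_pip3:
        raise ModelConfigError(
            "PIP3 forcing replaces s*S and applies to WP/WPI only; "
            "the WPI-PIP3 variant evolves its own PIP3 equation")

    rest = compute_rest_state(params)
    y0 = rest.as_array()

    if pip3_forcing is not None:
        force = _forcing_interpolator(pip3_forcing.times, pip3_forcing.pip3, t_end)
        breakpoints = np.asarray(pip3_forcing.times, dtype=float)

        def stim(t: float) -> float:
            return force(t)
    else:
        if protocol is None:
            def stim(t: float) -> float:
                return 0.0
            breakpoints = np.array([])
        else:
            def stim(t: float) -> float:
                return float(protocol.evaluate(0.0, t))
            breakpoints = np.asarray(protocol.breakpoints(t_end), dtype=float)

    def rhs(t, y):
        u, v, h, p = y
        S = stim(t)
        act = params.k0 + float(hill_activation(max(u, 0.0), params))
        if params.has_pip3:
            act += params.k_p * p
        else:
            act += params.s * S
        dec = params.delta + (params.k1 * h if params.has_inhibitor else 0.0)
        du = act * v - dec * u
        dh = params.alpha * u - params.delta_h * h if params.has_inhibitor else 0.0
        dp = params.s_p * S - params.delta_p * p if params.has_pip3 else 0.0
        return (du, -du, dh, dp)

    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_eval = t_eval[t_eval <= t_end]
    # split the run at stimulus discontinuities so the adaptive stepper
    # never straddles a switch
    cuts = np.unique(np.concatenate(
        [[0.0, t_end], breakpoints[(breakpoints > 0) & (breakpoints < t_end)]]))
    out = np.empty((4, len(t_eval)))
    out[:, 0] = y0
    filled = 1
    y = y0.copy()
    for a, b in zip(cuts[:-1], cuts[1:]):
        seg = t_eval[(t_eval > a) & (t_eval <= b)]
        pts = np.unique(np.concatenate([seg, [b]]))
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=pts,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        y = sol.y[:, -1]
        out[:, filled:filled + len(seg)] = sol.y[:, np.isin(sol.t, seg)]
        filled += len(seg)
    assert filled == len(t_eval)
    u, v, h, p = out
    return Trajectory(times=t_eval, u=u / rest.u, v=v, h=h, p=p,
                      u_rest=rest.u)


def experiment_step_vs_ramp(params: ModelParams,
                            amplitude: float = 0.1,
                            t_on: float = 60.0,
                            ramp_duration: float = 600.0,
                            t_end: float = 900.0,
                            dt_out: float = 2.0) -> dict:
    """Well-mixed rate-sensing comparison: abrupt step versus slow ramp to
    the same final stimulus level.

    The inhibitor circuit is excitable: a step of moderate amplitude fires
    a large transient Rac spike before the slow inhibitor catches up,
    while a ramp slower than the inhibitor timescale lets the inhibitor
    track the input, producing only a mild graded rise.  The default
    amplitude sits in the band where this contrast is sharpest; large
    amplitudes eventually fire even under slow ramps (the dynamic
    threshold is finite).

    Returns the two trajectories plus their overshoot ratios
    ``(max - final) / final``.
    """
    from .stimulus import protocol_global_ramp, protocol_global_step

    step = integrate_well_mixed(
        params, protocol_global_step(t_on=t_on, amplitude=amplitude),
        t_end=t_end, dt_out=dt_out)
    ramp = integrate_well_mixed(
        params, protocol_global_ramp(t_on=t_on, duration=ramp_duration,
                                     amplitude=amplitude),
        t_end=t_end, dt_out=dt_out)

    def overshoot(traj):
        return float((traj.u.max() - traj.u[-1]) / traj.u[-1])

    return {"step": step, "ramp": ramp,
            "step_overshoot": overshoot(step),
            "ramp_overshoot": overshoot(ramp)}


def integrate_well_mixed_rk4(
    params: ModelParams,
    protocol=None,
    t_end: float = 480.0,
    dt: float = 1e-3,
    dt_out: float = 5.0,
    pip3_forcing=None,
) -> Trajectory:
    """Fixed-step classical RK4 reference integrator (for cross-checking the
    adaptive path; slow at small dt)."""
    rest = compute_rest_state(params)
    if pip3_forcing is not None:
        force = _forcing_interpolator(pip3_forcing.times, pip3_forcing.pip3, t_end)

        def stim(t):
            return force(t)
    elif protocol is not None:
        def stim(t):
            return float(protocol.evaluate(0.0, t))
    else:
        def stim(t):
            return 0.0

    def f(t, y):
        u, v, h, p = y
        S = stim(t)
        act = params.k0 + float(hill_activation(max(u, 0.0), params))
        if params.has_pip3:
            act += params.k_p * p
        else:
            act += params.s * S
        dec = params.delta + (params.k1 * h if params.has_inhibitor else 0.0)
        du = act * v - dec * u
        dh = params.alpha * u - params.delta_h * h if params.has_inhibitor else 0.0
        dp = params.s_p * S - params.delta_p * p if params.has_pip3 else 0.0
        return np.array([du, -du, dh, dp])

    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_eval = t_eval[t_eval <= t_end]
    # march in segments aligned with both the output times and any stimulus
    # discontinuities, so no fixed step straddles a switch
    if pip3_forcing is not None:
        bps = np.asarray(pip3_forcing.times, dtype=float)
    elif protocol is not None:
        bps = np.asarray(protocol.breakpoints(t_end), dtype=float)
    else:
        bps = np.array([])
    knots = np.unique(np.concatenate(
        [t_eval, bps[(bps > 0) & (bps < t_end)], [t_end]]))
    y = rest.as_array()
    out = np.empty((4, len(t_eval)))
    out[:, 0] = y
    next_out = 1
    for a, b in zip(knots[:-1], knots[1:]):
        n_steps = max(1, int(math.ceil((b - a) / dt - 1e-12)))
        h_step = (b - a) / n_steps
        t = a
        for _ in range(n_steps):
            # the end-of-step stage stays left of the segment boundary so a
            # right-continuous switch at b never leaks into this segment
            t_hi = min(t + h_step, b - 1e-9)
            k1 = f(t, y)
            k2 = f(t + h_step / 2, y + h_step / 2 * k1)
            k3 = f(t + h_step / 2, y + h_step / 2 * k2)
            k4 = f(t_hi, y + h_step * k3)
            y = y + h_step / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h_step
        while next_out < len(t_eval) and b >= t_eval[next_out] - 1e-9:
            out[:, next_out] = y
            next_out += 1
    u, v, h, p = out
    return Trajectory(times=t_eval, u=u / rest.u, v=v, h=h, p=p, u_rest=rest.u)
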