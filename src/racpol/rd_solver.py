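"""Reaction-diffusion solver on the periodic 1D cell edge.

The cell perimeter is a ring of ``n_bins`` equal angular bins (degrees,
compass frame: 0 = north, counterclockwise positive, wrapped to
[-180, 180)).  Diffusion uses the length coordinate x = L * angle/360, with
``D_u = 1`` setting the length unit.

Time stepping is Strang splitting: a Crank-Nicolson half-step of diffusion
(applied spectrally — the periodic Laplacian is circulant, so CN is an exact
per-mode rational multiplier), a full RK4 step of the reactions, and a second
diffusion half-step.  Both sub-steps conserve total Rac to round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .core_models import ModelParams, Variant, compute_rest_state

DEFAULT_N_BINS = 100
DEFAULT_L = 80.0  # perimeter, length units with D_u = 1
DEFAULT_DT = 0.05  # s


@dataclass(frozen=True)
class EdgeGrid:
    """Uniform periodic grid of edge-angle bins."""

    n_bins: int = DEFAULT_N_BINS
    L: float = DEFAULT_L

    def __post_init__(self) -> None:
        if self.n_bins < 16:
            raise ValueError("n_bins must be at least 16")
        if self.L <= 0:
            raise ValueError("perimeter L must be positive")

    @property
    def dtheta(self) -> float:
        return 360.0 / self.n_bins

    @property
    def dx(self) -> float:
        return self.L / self.n_bins

    @property
    def theta(self) -> np.ndarray:
        """Bin centers in [-180, 180)."""
        return -180.0 + (np.arange(self.n_bins) + 0.5) * self.dtheta

    def bin_of(self, theta) -> np.ndarray:
        """Bin index containing angle(s) theta (degrees, any branch)."""
        wrapped = (np.asarray(theta, dtype=float) + 180.0) % 360.0
        idx = np.floor(wrapped / self.dtheta).astype(int)
        return np.clip(idx, 0, self.n_bins - 1)


@dataclass
class EdgeState:
    """Concentration fields on the ring at one time."""

    u: np.ndarray
    v: np.ndarray
    h: np.ndarray
    p: np.ndarray
    t: float = 0.0

    def copy(self) -> "EdgeState":
        return EdgeState(self.u.copy(), self.v.copy(), self.h.copy(),
                         self.p.copy(), self.t)


@dataclass
class Kymograph:
    """time x angle matrix of one field."""

    times: np.ndarray
    theta: np.ndarray
    values: np.ndarray
    field: str = "u"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.times), len(self.theta)):
            raise ValueError("kymograph shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kymograph contains non-finite values")

    def to_dataframe(self) -> pd.DataFrame:
        tt, aa = np.meshgrid(self.times, self.theta, indexing="ij")
        return pd.DataFrame({
            "time_s": tt.ravel(), "angle_deg": aa.ravel(),
            "value": self.values.ravel(), "field": self.field,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_png(self, path, cmap: str = "viridis") -> None:
        """Render the kymograph (time on the vertical axis) to a PNG."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        extent = [self.theta[0], self.theta[-1],
                  self.times[-1], self.times[0]]
        im = ax.imshow(self.values, aspect="auto", extent=extent, cmap=cmap)
        ax.set_xlabel("edge angle (deg)")
        ax.set_ylabel("time (s)")
        ax.set_title(self.field)
        fig.colorbar(im, ax=ax, label=self.field)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def periodic_laplacian(field_values: np.ndarray, grid: EdgeGrid) -> np.ndarray:
    """Second-order central-difference Laplacian with periodic wrap.

    The discrete operator telescopes, so the output sums to zero (mass is
    conserved by diffusion).
    """
    f = np.asarray(field_values, dtype=float)
    if f.shape != (grid.n_bins,):
        raise ValueError("field length must equal grid.n_bins")
    return (np.roll(f, -1) - 2.0 * f + np.roll(f, 1)) / grid.dx ** 2


class SolverBlowupError(RuntimeError):
    """The PDE state became non-finite."""


class EdgeSimulator:
    """Stepwise integrator for one model variant on a ring.

    ``stim_fn(theta_array, t) -> S_array`` provides the light field; by
    default it evaluates a :class:`~racpol.stimulus.StimulusProtocol`.
    Drivers (e.g. the motility layer) may swap ``stim_fn`` between steps.
    """

    def __init__(self, params: ModelParams, grid: EdgeGrid,
                 stim_fn: Optional[Callable] = None,
                 initial: Optional[EdgeState] = None,
                 dt: float = DEFAULT_DT):
        self.params = params
        self.grid = grid
        self.dt = float(dt)
        self.stim_fn = stim_fn or (lambda theta, t: np.zeros_like(theta))
        if initial is None:
            rest = compute_rest_state(params)
            n = grid.n_bins
            initial = EdgeState(np.full(n, rest.u), np.full(n, rest.v),
                                np.full(n, rest.h), np.full(n, rest.p), 0.0)
        self.state = initial.copy()
        self.u_rest = float(compute_rest_state(params).u)
        self._mass0 = float(np.mean(self.state.u) + np.mean(self.state.v))
        self._prepare_diffusion(self.dt)

    def _prepare_diffusion(self, dt: float) -> None:
        n = self.grid.n_bins
        # eigenvalues of the periodic central-difference Laplacian
        k = np.arange(n // 2 + 1)
        lam = (2.0 * np.cos(2.0 * np.pi * k / n) - 2.0) / self.grid.dx ** 2
        self._cn = {}
        p = self.params
        coeffs = {"u": p.D_u, "v": p.D_v}
        if p.has_inhibitor:
            coeffs["h"] = p.D_h
        if p.has_pip3:
            coeffs["p"] = p.D_p
        for name, D in coeffs.items():
            a = 0.5 * dt * D * lam / 2.0  # half-step CN
            self._cn[name] = (1.0 + a) / (1.0 - a)

    def _diffuse_half(self) -> None:
        st = self.state
        for name, mult in self._cn.items():
            f = getattr(st, name)
            setattr(st, name, np.fft.irfft(np.fft.rfft(f) * mult, n=self.grid.n_bins))

    def _reaction_rhs(self, u, v, h, p, S):
        prm = self.params
        act = prm.k0 + prm.gamma * u ** prm.n / (prm.K ** prm.n + u ** prm.n)
        if prm.has_pip3:
            act = act + prm.k_p * p
        else:
            act = act + prm.s * S
        dec = prm.delta + (prm.k1 * h if prm.has_inhibitor else 0.0)
        du = act * v - dec * u
        dh = prm.alpha * u - prm.delta_h * h if prm.has_inhibitor else 0.0
        dp = prm.s_p * S - prm.delta_p * p if prm.has_pip3 else 0.0
        return du, dh, dp

    def _react(self, dt: float) -> None:
        st = self.state
        theta = self.grid.theta
        t = st.t
        u, v, h, p = st.u, st.v, st.h, st.p
        S0 = np.maximum(np.asarray(self.stim_fn(theta, t), dtype=float), 0.0)
        Sh = np.maximum(np.asarray(self.stim_fn(theta, t + dt / 2), dtype=float), 0.0)
        S1 = np.maximum(np.asarray(self.stim_fn(theta, t + dt), dtype=float), 0.0)
        # classical RK4 on (u, h, p); v follows from conservation
        du1, dh1, dp1 = self._reaction_rhs(u, v, h, p, S0)
        u2 = u + dt / 2 * du1
        du2, dh2, dp2 = self._reaction_rhs(
            u2, v - dt / 2 * du1, h + dt / 2 * dh1, p + dt / 2 * dp1, Sh)
        u3 = u + dt / 2 * du2
        du3, dh3, dp3 = self._reaction_rhs(
            u3, v - dt / 2 * du2, h + dt / 2 * dh2, p + dt / 2 * dp2, Sh)
        u4 = u + dt * du3
        du4, dh4, dp4 = self._reaction_rhs(
            u4, v - dt * du3, h + dt * dh3, p + dt * dp3, S1)
        du = dt / 6 * (du1 + 2 * du2 + 2 * du3 + du4)
        st.u = u + du
        st.v = v - du
        st.h = h + dt / 6 * (dh1 + 2 * dh2 + 2 * dh3 + dh4)
        st.p = p + dt / 6 * (dp1 + 2 * dp2 + 2 * dp3 + dp4)

    def step(self) -> None:
        """Advance one Strang-split time step."""
        self._diffuse_half()
        self._react(self.dt)
        self._diffuse_half()
        self.state.t += self.dt
        if not np.all(np.isfinite(self.state.u)):
            raise SolverBlowupError(
                f"non-finite active Rac at t = {self.state.t:.2f} s")

    def advance(self, duration: float) -> None:
        n = int(round(duration / self.dt))
        for _ in range(n):
            self.step()

    @property
    def mass_error(self) -> float:
        """Relative drift of total Rac on the ring."""
        mass = float(np.mean(self.state.u) + np.mean(self.state.v))
        return abs(mass - self._mass0) / self._mass0


@dataclass
class EdgeRun:
    """Output of a full edge simulation: one kymograph per field."""

    u: Kymograph
    v: Kymograph
    h: Optional[Kymograph]
    p: Optional[Kymograph]
    S: Kymograph
    u_rest: float

    def __getitem__(self, name: str) -> Kymograph:
        out = getattr(self, name)
        if out is None:
            raise KeyError(f"field {name} not present in this run")
        return out


def simulate_edge(params: ModelParams, grid: Optional[EdgeGrid] = None,
                  protocol=None, t_end: float = 600.0, dt_out: float = 2.0,
                  initial: Optional[EdgeState] = None,
                  dt: float = DEFAULT_DT) -> EdgeRun:
    """Run the spatial model and return kymographs of all fields plus S.

    Starts from the spatially uniform rest state unless ``initial`` is
    given.  Total Rac on the ring is conserved to round-off by the scheme;
    the ``EdgeSimulator.mass_error`` diagnostic exposes the drift.
    """
    grid = grid or EdgeGrid()
    if protocol is not None:
        stim_fn = lambda theta, t: protocol.evaluate(theta, t)
    else:
        stim_fn = None
    sim = EdgeSimulator(params, grid, stim_fn=stim_fn, initial=initial, dt=dt)
    n_out = int(math.floor(t_end / dt_out + 1e-9)) + 1
    times = np.arange(n_out) * dt_out
    theta = grid.theta
    rows_u, rows_v, rows_h, rows_p, rows_s = [], [], [], [], []

    def snapshot():
        st = sim.state
        rows_u.append(st.u.copy())
        rows_v.append(st.v.copy())
        rows_h.append(st.h.copy())
        rows_p.append(st.p.copy())
        S = sim.stim_fn(theta, st.t)
        rows_s.append(np.maximum(np.asarray(S, dtype=float), 0.0))

    snapshot()
    steps_per_out = int(round(dt_out / dt))
    if abs(steps_per_out * dt - dt_out) > 1e-9:
        raise ValueError("dt_out must be a multiple of dt")
    for _ in range(n_out - 1):
        for _ in range(steps_per_out):
            sim.step()
        snapshot()

    def kymo(rows, name):
        return Kymograph(times=times, theta=theta,
                         values=np.asarray(rows), field=name)

    return EdgeRun(
        u=kymo(rows_u, "u"), v=kymo(rows_v, "v"),
        h=kymo(rows_h, "h") if params.has_inhibitor else None,
        p=kymo(rows_p, "p") if params.has_pip3 else None,
        S=kymo(rows_s, "S"), u_rest=sim.u_rest)


def experiment_competing_stimuli(params: ModelParams, mode: str,
                                 grid: Optional[EdgeGrid] = None,
                                 t_second: float = 400.0,
                                 eval_window: float = 75.0,
                                 amplitude: float = 3.0,
                                 width_deg: float = 45.0,
                                 init_ramp: float = 150.0,
                                 ramp_duration: float = 900.0,
                                 dt_out: float = 5.0) -> EdgeRun:
    """Rate-sensing on the ring: a held Rac zone versus a competing patch.

    A Gaussian patch at -90 deg is ramped in gently over ``init_ramp``
    seconds (an abrupt hold onset flings a transient wave around the ring)
    and then held constant, parking the Rac zone at -90 deg.  At
    ``t_second`` a second, equal-strength patch at +90 deg arrives either
    abruptly (``mode="step"``) or as a slow ramp reaching full strength
    over ``ramp_duration`` seconds.  The run ends ``eval_window`` seconds
    after the second onset: by then an abrupt competitor has relocated the
    Rac peak to +90 deg, while a gradual one leaves it at -90 deg — the
    inhibitor filters out slowly growing inputs.

    On much longer horizons inhibitor accumulation makes any held zone hop
    regardless of stimulation rate, so the discrimination is read out
    within this window.
    """
    import warnings

    from .stimulus import (Component, Gaussian, Ramp, Step,
                           StimulusProtocol)

    if Variant.coerce(params.variant) is not Variant.WPI:
        warnings.warn("competing-stimulus behavior is characterized for the "
                      "WPI variant; results for other variants are not "
                      "calibrated", stacklevel=2)
    hold = Component(Gaussian(-90.0, width_deg),
                     Ramp(0.0, amplitude / init_ramp, amplitude), 1.0)
    if mode == "step":
        second = Component(Gaussian(90.0, width_deg), Step(t_second), amplitude)
    elif mode == "ramp":
        second = Component(Gaussian(90.0, width_deg),
                           Ramp(t_second, amplitude / ramp_duration, amplitude),
                           1.0)
    else:
        raise ValueError("mode must be 'step' or 'ramp'")
    protocol = StimulusProtocol((hold, second), name=f"competing_{mode}")
    grid = grid or EdgeGrid(n_bins=100, L=60.0)
    return simulate_edge(params, grid=grid, protocol=protocol,
                         t_end=t_second + eval_window, dt_out=dt_out)
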