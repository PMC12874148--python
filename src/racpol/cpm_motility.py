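"""Cellular-Potts cell whose protrusion is biased by edge-resolved Rac.

A single cell on a square lattice evolves by Metropolis-accepted pixel
copy attempts under an energy with area, perimeter and adhesion terms.
The reaction-diffusion ring (one of the three Rac circuits) is solved on a
fixed set of edge-angle bins; each boundary pixel reads the active-Rac
level of the bin containing its polar angle about the centroid, and the
work term ``-lambda_Rac * (u - mean(u))`` favors extension where Rac is
high and retraction where it is low.  High-Rac edge therefore becomes the
cell front, and the centroid track records the resulting motility.

Angles are compass degrees (0 = north/up, counterclockwise positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Tuple

import numpy as np
import pandas as pd
from numba import njit

from .core_models import ModelParams, Variant, load_preset
from .rd_solver import EdgeGrid, EdgeSimulator, Kymograph
from .stimulus import Gaussian, StimulusProtocol, wrap_angle


@dataclass(frozen=True)
class CpmConfig:
    """Lattice and energy parameters of the Potts cell."""

    lattice: int = 200  # pixels per side
    target_area: float = 500.0  # A0, px^2
    lambda_area: float = 0.2
    target_perimeter: float = 110.0  # P0, 4-neighbor boundary links
    lambda_perimeter: float = 0.02
    adhesion_j: float = 0.4  # energy per cell-medium link
    temperature: float = 2.0
    lambda_rac: float = 4.0  # protrusion coupling to (u - mean u), per AU
    mcs_per_second: float = 1.0
    reaim_interval: float = 5.0  # s between front-relative stimulus re-aims
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lambda_area, self.lambda_perimeter) < 0:
            raise ValueError("stiffnesses must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.mcs_per_second <= 0:
            raise ValueError("mcs_per_second must be positive")


@dataclass
class CellTrack:
    """Centroid track with edge-front annotation and rotation labels."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray  # y increases northward (up)
    front_angle: np.ndarray  # argmax of edge u, compass deg
    heading: np.ndarray  # direction of smoothed motion, compass deg (NaN if still)
    rotation: Optional[List[str]] = None  # per-window labels, filled by analysis

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times, "x": self.x, "y": self.y,
            "front_angle_deg": self.front_angle, "heading_deg": self.heading,
        })


# ---------------------------------------------------------------------------
# lattice kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _local_blocks(nb):
    """Number of cyclic blocks of occupied pixels in an 8-neighborhood ring
    (ordered N, NE, E, SE, S, SW, W, NW)."""
    blocks = 0
    for i in range(8):
        if nb[i] == 1 and nb[(i + 1) % 8] == 0:
            blocks += 1
    return blocks


@njit(cache=True)
def _mcs(lat, n_attempts, A, P, sx, sy, u_bins, u_mean, n_bins,
         A0, lamA, P0, lamP, J, T, lam_rac, seed):
    """One batch of Metropolis copy attempts.  Returns updated
    (A, P, sx, sy); ``lat`` is modified in place.

    sx, sy are coordinate sums of cell pixels (centroid bookkeeping);
    columns = x (east), rows = y index (south), the caller converts to
    northward y.
    """
    np.random.seed(seed)
    L = lat.shape[0]
    cx = sx / A
    cy = sy / A
    for _ in range(n_attempts):
        r = 1 + int(np.random.random() * (L - 2))
        c = 1 + int(np.random.random() * (L - 2))
        if r >= L - 1 or c >= L - 1:
            continue
        me = lat[r, c]
        # pick a random 4-neighbor
        k = int(np.random.random() * 4)
        if k == 0:
            r2, c2 = r - 1, c
        elif k == 1:
            r2, c2 = r + 1, c
        elif k == 2:
            r2, c2 = r, c - 1
        else:
            r2, c2 = r, c + 1
        other = lat[r2, c2]
        if me == other:
            continue
        # flipping (r, c) to `other`
        ncell = lat[r - 1, c] + lat[r + 1, c] + lat[r, c - 1] + lat[r, c + 1]
        if other == 1:
            dA = 1.0
            dP = 4.0 - 2.0 * ncell
        else:
            dA = -1.0
            dP = 2.0 * ncell - 4.0
        if A + dA < 8.0:
            continue
        # local connectivity: the flipped pixel must be a "simple" point for
        # both the cell and the medium (no splitting, no holes)
        nb = np.empty(8, dtype=np.int8)
        nb[0] = lat[r - 1, c]
        nb[1] = lat[r - 1, c + 1]
        nb[2] = lat[r, c + 1]
        nb[3] = lat[r + 1, c + 1]
        nb[4] = lat[r + 1, c]
        nb[5] = lat[r + 1, c - 1]
        nb[6] = lat[r, c - 1]
        nb[7] = lat[r - 1, c - 1]
        if _local_blocks(nb) != 1:
            continue
        inv = 1 - nb
        if _local_blocks(inv) != 1:
            continue
        dH = lamA * ((A + dA - A0) ** 2 - (A - A0) ** 2) \
            + lamP * ((P + dP - P0) ** 2 - (P - P0) ** 2) \
            + J * dP
        # Rac work term at the pixel's edge angle about the centroid
        dx = c - cx
        dy = -(r - cy)  # northward
        ang = math.degrees(math.atan2(dy, dx)) - 90.0  # compass, CCW+
        ang = (ang + 540.0) % 360.0  # -> [0, 360)
        b = int(ang / (360.0 / n_bins))
        if b >= n_bins:
            b = n_bins - 1
        work = lam_rac * (u_bins[b] - u_mean)
        if other == 1:
            dH -= work  # extension into high-Rac edge is favored
        else:
            dH += work  # retraction of high-Rac edge is penalized
        if dH <= 0.0 or np.random.random() < math.exp(-dH / T):
            lat[r, c] = other
            A += dA
            P += dP
            if other == 1:
                sx += c
                sy += r
            else:
                sx -= c
                sy -= r
            cx = sx / A
            cy = sy / A
    return A, P, sx, sy


def _disk_mask(lattice: int, area: float) -> np.ndarray:
    radius = math.sqrt(area / math.pi)
    rr, cc = np.mgrid[0:lattice, 0:lattice]
    mid = lattice / 2.0 - 0.5
    return ((rr - mid) ** 2 + (cc - mid) ** 2 <= radius ** 2).astype(np.int8)


def _count_perimeter(lat: np.ndarray) -> int:
    p = 0
    p += int(np.sum(lat[1:, :] != lat[:-1, :]))
    p += int(np.sum(lat[:, 1:] != lat[:, :-1]))
    return p


def boundary_pixels(lat: np.ndarray) -> np.ndarray:
    """(row, col) of cell pixels with at least one medium 4-neighbor."""
    cell = lat == 1
    pad = np.pad(cell, 1, constant_values=False)
    nb = (~pad[:-2, 1:-1] | ~pad[2:, 1:-1] | ~pad[1:-1, :-2] | ~pad[1:-1, 2:])
    edge = cell & nb
    return np.argwhere(edge)


def pixel_angles(pixels: np.ndarray, centroid_rc: Tuple[float, float]) -> np.ndarray:
    """Compass angle of each (row, col) pixel about the centroid."""
    dy = -(pixels[:, 0] - centroid_rc[0])
    dx = pixels[:, 1] - centroid_rc[1]
    return wrap_angle(np.degrees(np.arctan2(dy, dx)) - 90.0)


def map_edge_to_ring(mask: np.ndarray, grid: EdgeGrid,
                     values: Optional[np.ndarray] = None) -> np.ndarray:
    """Assign every angle bin a value read from the boundary pixels.

    ``values`` holds one value per boundary pixel (same order as
    :func:`boundary_pixels`); by default the pixel count per bin is
    returned.  Bins with no boundary pixel are filled by nearest occupied
    bin around the ring, so every bin is readable.
    """
    pix = boundary_pixels(mask)
    if len(pix) == 0:
        raise ValueError("mask has no boundary pixels (empty cell?)")
    rows, cols = np.nonzero(mask)
    centroid = (rows.mean(), cols.mean())
    ang = pixel_angles(pix, centroid)
    bins = grid.bin_of(ang)
    n = grid.n_bins
    if values is None:
        out = np.bincount(bins, minlength=n).astype(float)
        have = out > 0
    else:
        sums = np.bincount(bins, weights=values, minlength=n)
        cnts = np.bincount(bins, minlength=n)
        have = cnts > 0
        out = np.zeros(n)
        out[have] = sums[have] / cnts[have]
    if not np.all(have):
        idx_have = np.nonzero(have)[0]
        for i in np.nonzero(~have)[0]:
            d = np.minimum((idx_have - i) % n, (i - idx_have) % n)
            out[i] = out[idx_have[np.argmin(d)]]
    return out


# ---------------------------------------------------------------------------
# coupled simulation
# ---------------------------------------------------------------------------

class CpmCell:
    """Potts-lattice state plus bookkeeping for one cell."""

    def __init__(self, config: CpmConfig):
        self.config = config
        self.lat = _disk_mask(config.lattice, config.target_area)
        self.area = float(self.lat.sum())
        self.perimeter = float(_count_perimeter(self.lat))
        rows, cols = np.nonzero(self.lat)
        self.sx = float(cols.sum())
        self.sy = float(rows.sum())

    @property
    def centroid_rc(self) -> Tuple[float, float]:
        return (self.sy / self.area, self.sx / self.area)

    @property
    def centroid_xy(self) -> Tuple[float, float]:
        """(x east, y north) with y measured upward from the south edge."""
        r, c = self.centroid_rc
        return (c, self.lat.shape[0] - 1 - r)

    def sweep(self, n_mcs: int, u_bins: np.ndarray, n_bins: int,
              rng: np.random.Generator) -> None:
        cfg = self.config
        n_attempts = cfg.lattice * cfg.lattice
        for _ in range(max(1, int(round(n_mcs)))):
            seed = int(rng.integers(0, 2 ** 31 - 1))
            self.area, self.perimeter, self.sx, self.sy = _mcs(
                self.lat, n_attempts, self.area, self.perimeter,
                self.sx, self.sy, u_bins, float(np.mean(u_bins)), n_bins,
                cfg.target_area, cfg.lambda_area, cfg.target_perimeter,
                cfg.lambda_perimeter, cfg.adhesion_j, cfg.temperature,
                cfg.lambda_rac, seed)


def front_angle_of(u: np.ndarray, theta: np.ndarray) -> float:
    """Circular-mean direction of the active-Rac distribution."""
    z = np.sum(u * np.exp(1j * np.radians(theta)))
    return float(np.degrees(np.angle(z)))


@dataclass
class MotilityResult:
    track: CellTrack
    u_kymo: Kymograph
    s_kymo: Kymograph
    final_mask: np.ndarray
    mass_error: float
    area_series: np.ndarray
    switch_time: Optional[float] = None  # rotation-triggered global onset


def run_motility(params: "ModelParams | str",
                 protocol: Optional[StimulusProtocol] = None,
                 config: Optional[CpmConfig] = None,
                 duration: float = 600.0,
                 seed: int = 0,
                 grid: Optional[EdgeGrid] = None,
                 front_relative: Optional[dict] = None,
                 gradient: Optional[Callable] = None,
                 gradient_gain: float = 1.0,
                 init_polarity_deg: Optional[float] = None,
                 dt_record: float = 1.0,
                 stop_after_switch: Optional[float] = None) -> MotilityResult:
    """Coupled edge-RD + Potts run.

    Stimulus placement, one of:

    * ``protocol`` — lab-frame :class:`StimulusProtocol`;
    * ``front_relative`` — dict with keys ``side_deg`` (offset CCW from the
      current Rac front), ``t_on``, ``t_off``, optional ``amplitude``,
      ``width_deg``, ``global_from`` (uniform light from that time on); the
      patch is re-aimed every ``config.reaim_interval`` seconds;
    * ``gradient`` — callable ``c(x, y, t)`` giving attractant
      concentration at lattice coordinates; each edge bin converts the
      concentration at its boundary pixel into local activation
      ``S = gradient_gain * c``.

    ``init_polarity_deg`` seeds a polarized Rac zone by a brief local
    pre-stimulus at that compass angle before t = 0.
    """
    if isinstance(params, str):
        params = load_preset(params)
    config = config or CpmConfig()
    if grid is None:
        grid = EdgeGrid(100, 32.0 if params.variant is Variant.WP else 80.0)
    rng = np.random.default_rng(seed)
    cell = CpmCell(config)

    edge = EdgeSimulator(params, grid)
    theta = grid.theta
    if init_polarity_deg is not None:
        g = Gaussian(init_polarity_deg)
        amp = 1.0 if params.variant is not Variant.WPI_PIP3 else 1.0
        edge.stim_fn = lambda th, t: amp * g(th)
        edge.advance(60.0 if not params.has_pip3 else 120.0)
        edge.stim_fn = lambda th, t: np.zeros_like(th)
        edge.advance(10.0)
        edge.state.t = 0.0

    aim = {"target": None, "last": -math.inf, "prev_front": None,
           "rot": 0.0, "switched_at": None}
    grad_cache = {"S": np.zeros(grid.n_bins)}

    def refresh_gradient(t):
        # boundary geometry changes on the MCS timescale; sampling the
        # attractant field once per record step is ample
        grad_cache["S"] = _gradient_stimulus(cell, grid, gradient,
                                             gradient_gain, t)

    def stim_fn(th, t):
        if gradient is not None:
            return grad_cache["S"]
        if front_relative is not None:
            fr = front_relative
            if not (fr["t_on"] <= t):
                return np.zeros_like(th)
            gl = fr.get("global_from", math.inf)
            rot_trigger = fr.get("switch_rotation_deg")
            if aim["switched_at"] is not None:
                gl = min(gl, aim["switched_at"])
            if t >= gl:
                return np.full_like(th, fr.get("amplitude", 1.0))
            if t >= fr.get("t_off", math.inf):
                return np.zeros_like(th)
            if aim["target"] is None or t - aim["last"] >= config.reaim_interval:
                fa = front_angle_of(edge.state.u, theta)
                if aim["prev_front"] is not None:
                    aim["rot"] += float(wrap_angle(fa - aim["prev_front"]))
                aim["prev_front"] = fa
                aim["target"] = fa + fr["side_deg"]
                aim["last"] = t
                if rot_trigger is not None and abs(aim["rot"]) >= rot_trigger:
                    # accumulated rotation reached: hand over to global light
                    aim["switched_at"] = t
                    return np.full_like(th, fr.get("amplitude", 1.0))
            g = Gaussian(aim["target"], fr.get("width_deg", 30.0))
            return fr.get("amplitude", 1.0) * g(th)
        if protocol is not None:
            return protocol.evaluate(th, t)
        return np.zeros_like(th)

    edge.stim_fn = stim_fn

    n_rec = int(round(duration / dt_record)) + 1
    times = np.arange(n_rec) * dt_record
    xs = np.empty(n_rec)
    ys = np.empty(n_rec)
    fronts = np.empty(n_rec)
    areas = np.empty(n_rec)
    u_rows, s_rows = [], []
    if gradient is not None:
        refresh_gradient(0.0)
    x0, y0 = cell.centroid_xy
    xs[0], ys[0] = x0, y0
    fronts[0] = front_angle_of(edge.state.u, theta)
    areas[0] = cell.area
    u_rows.append(edge.state.u.copy())
    s_rows.append(np.maximum(np.asarray(stim_fn(theta, 0.0), float), 0.0))

    mcs_acc = 0.0
    n_done = n_rec
    for i in range(1, n_rec):
        if stop_after_switch is not None and aim["switched_at"] is not None \
                and times[i] > aim["switched_at"] + stop_after_switch:
            n_done = i  # truncate: everything after the window is unused
            break
        if gradient is not None:
            refresh_gradient(edge.state.t)
        edge.advance(dt_record)
        mcs_acc += config.mcs_per_second * dt_record
        n_mcs = int(mcs_acc)
        mcs_acc -= n_mcs
        if n_mcs:
            cell.sweep(n_mcs, edge.state.u, grid.n_bins, rng)
        xs[i], ys[i] = cell.centroid_xy
        fronts[i] = front_angle_of(edge.state.u, theta)
        areas[i] = cell.area
        u_rows.append(edge.state.u.copy())
        s_rows.append(np.maximum(np.asarray(stim_fn(theta, edge.state.t), float), 0.0))

    times = times[:n_done]
    xs, ys, fronts, areas = xs[:n_done], ys[:n_done], fronts[:n_done], \
        areas[:n_done]
    u_rows, s_rows = u_rows[:n_done], s_rows[:n_done]
    heading = _headings(times, xs, ys)
    track = CellTrack(times=times, x=xs, y=ys, front_angle=fronts,
                      heading=heading)
    return MotilityResult(
        track=track,
        u_kymo=Kymograph(times=times, theta=theta, values=np.asarray(u_rows),
                         field="u"),
        s_kymo=Kymograph(times=times, theta=theta, values=np.asarray(s_rows),
                         field="S"),
        final_mask=cell.lat.copy(),
        mass_error=edge.mass_error,
        area_series=areas,
        switch_time=aim["switched_at"])


def _gradient_stimulus(cell: CpmCell, grid: EdgeGrid, gradient: Callable,
                       gain: float, t: float) -> np.ndarray:
    pix = boundary_pixels(cell.lat)
    if len(pix) == 0:
        return np.zeros(grid.n_bins)
    Lside = cell.lat.shape[0]
    xvals = pix[:, 1].astype(float)
    yvals = (Lside - 1 - pix[:, 0]).astype(float)
    conc = np.maximum(np.asarray(gradient(xvals, yvals, t), dtype=float), 0.0)
    return np.maximum(map_edge_to_ring(cell.lat, grid, values=gain * conc), 0.0)


def _headings(times: np.ndarray, xs: np.ndarray, ys: np.ndarray,
              window: float = 20.0, min_step: float = 2.0) -> np.ndarray:
    """Compass direction of motion from displacement over a trailing
    window; NaN where the cell has not moved appreciably."""
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    k = max(1, int(round(window / dt)))
    heading = np.full(len(times), np.nan)
    for i in range(len(times)):
        j = max(0, i - k)
        dx = xs[i] - xs[j]
        dy = ys[i] - ys[j]
        if math.hypot(dx, dy) >= min_step:
            heading[i] = wrap_angle(math.degrees(math.atan2(dy, dx)) - 90.0)
    return heading


# ---------------------------------------------------------------------------
# phenotype experiments
# ---------------------------------------------------------------------------

#: chasing-patch offset ahead of the Rac front, per variant.  The
#: experimental light acts through PI3K/PIP3; the WP/WPI models collapse
#: that intermediate into a direct Rac-activation term, so their patch is
#: placed closer ahead to give a comparable effective activation offset.
CHASE_LEAD_DEG = {Variant.WP: 45.0, Variant.WPI: 45.0,
                  Variant.WPI_PIP3: 90.0}
#: accumulated front rotation at which the local phase hands over to the
#: global stimulus, per variant.  The chase accelerates as it spins up.
#: WPI continuation needs a mature inhibitor trail (later hand-over);
#: WPI-PIP3 reversal needs the hand-over while rotation is still slow, so
#: the PIP3 bump has not been smeared behind the front (trail smearing
#: grows with rotation speed).
SWITCH_ROTATION_DEG = {Variant.WP: 300.0, Variant.WPI: 400.0,
                       Variant.WPI_PIP3: 300.0}


def run_local_to_global(variant: "str | ModelParams", seed: int = 0,
                        config: Optional[CpmConfig] = None,
                        t_local_on: float = 100.0,
                        switch_rotation_deg: Optional[float] = None,
                        max_duration: float = 700.0,
                        post_duration: float = 200.0,
                        side_deg: Optional[float] = None) -> MotilityResult:
    """Local-to-global rotation experiment separating the three circuits.

    A Gaussian patch chases the Rac front at a fixed angular lead from
    ``t_local_on`` onward, driving rotation; once the front has swept
    ``switch_rotation_deg`` of accumulated rotation the light switches to
    uniform (global) illumination for ``post_duration`` seconds.  Tying the
    switch to accumulated rotation (rather than a clock) aligns the
    inhibitor/PIP3 trail geometry across cells with different rotation
    speeds; slow cells that never reach the trigger switch at
    ``max_duration - post_duration``.
    """
    params = load_preset(variant) if isinstance(variant, str) else variant
    if side_deg is None:
        side_deg = CHASE_LEAD_DEG[Variant.coerce(params.variant)]
    if switch_rotation_deg is None:
        switch_rotation_deg = SWITCH_ROTATION_DEG[Variant.coerce(params.variant)]
    t_cap = max_duration - post_duration
    fr = dict(side_deg=side_deg, t_on=t_local_on, global_from=t_cap,
              switch_rotation_deg=switch_rotation_deg, amplitude=1.0)
    res = run_motility(params, config=config, duration=max_duration,
                       seed=seed, front_relative=fr, init_polarity_deg=0.0,
                       stop_after_switch=post_duration)
    if res.switch_time is None:
        res.switch_time = t_cap
    return res


def run_local_to_global_cohort(variant: str, n_cells: int = 20,
                               seed: int = 0,
                               heterogeneity_cv: float = 0.1,
                               config: Optional[CpmConfig] = None,
                               **kwargs) -> List[MotilityResult]:
    """Cohort of local-to-global runs with per-cell parameter heterogeneity
    (lognormal, like the synthetic-data generator)."""
    from .synthetic_data import _sample_params

    base = load_preset(variant)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_cells):
        prm = _sample_params(base, heterogeneity_cv, rng)
        cfg = config or CpmConfig()
        cfg = replace(cfg, seed=seed + i)
        out.append(run_local_to_global(prm, seed=seed + 17 * i + 1,
                                       config=cfg, **kwargs))
    return out


def run_gradient_experiment(variant: "str | ModelParams", seed: int = 0,
                            config: Optional[CpmConfig] = None,
                            duration: float = 400.0,
                            t_uniform: float = 80.0,
                            t_reversal: float = 120.0,
                            slope: float = 1.0,
                            noise_sd: float = 0.0,
                            gain: float = 1.0) -> MotilityResult:
    """North-pointing linear attractant gradient, reset to uniform at
    ``t_uniform`` and reversed (south-pointing) at ``t_reversal``.

    Optional additive spatial noise on the concentration field is redrawn
    every call (i.e. every reaction step), emulating a fluctuating
    environment.
    """
    params = load_preset(variant) if isinstance(variant, str) else variant
    config = config or CpmConfig()
    Lside = config.lattice
    rng = np.random.default_rng(seed + 999)

    def conc(x, y, t):
        yn = np.asarray(y, dtype=float) / Lside  # 0 (south) .. 1 (north)
        if t < t_uniform:
            c = 0.5 + slope * (yn - 0.5)
        elif t < t_reversal:
            c = np.full_like(yn, 0.5)
        else:
            c = 0.5 - slope * (yn - 0.5)
        if noise_sd > 0:
            c = c + rng.normal(0.0, noise_sd, size=np.shape(yn))
        return np.clip(c, 0.0, None)

    return run_motility(params, config=config, duration=duration, seed=seed,
                        gradient=conc, gradient_gain=gain,
                        init_polarity_deg=0.0)
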