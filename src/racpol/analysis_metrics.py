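"""Kymograph analytics, rotation metrics and parameter interpretation.

Peak tracking works on circular (edge-angle) data: per-time circular
argmax with parabolic sub-bin refinement, unwrapped across the +-180 deg
seam by always taking the smaller angular jump.  Rotation labels follow
the compass convention used throughout (CCW positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core_models import ModelParams, load_preset
from .stimulus import wrap_angle

#: winding (deg) per 100 s window needed to call a track "rotating"
ROTATION_THRESHOLD_DEG = 90.0
#: moving-mean width (s) for the reorientation-time velocity smoothing
REORIENT_SMOOTH_S = 20.0


@dataclass
class PeakTrack:
    """Angular position of a field's peak over time (unwrapped degrees)."""

    times: np.ndarray
    angle: np.ndarray  # unwrapped: consecutive jumps < 180 deg
    field: str = "u"
    peaked: bool = True  # False when the field was essentially uniform


def track_peak(kymo, min_contrast: float = 1.02) -> PeakTrack:
    """Track the circular argmax of a kymograph with sub-bin refinement.

    A frame whose max/min contrast is below ``min_contrast`` carries no
    meaningful peak; if that holds for most frames the track is flagged
    ``peaked=False`` (angles are still reported but are noise).
    """
    values = np.asarray(kymo.values, dtype=float)
    theta = np.asarray(kymo.theta, dtype=float)
    n = len(theta)
    dtheta = 360.0 / n
    raw = np.empty(len(values))
    contrasts = np.empty(len(values))
    for i, row in enumerate(values):
        j = int(np.argmax(row))
        y0, y1, y2 = row[(j - 1) % n], row[j], row[(j + 1) % n]
        denom = y0 - 2.0 * y1 + y2
        offset = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        offset = float(np.clip(offset, -0.5, 0.5))
        raw[i] = theta[j] + offset * dtheta
        lo = row.min()
        contrasts[i] = row.max() / lo if lo > 0 else np.inf
    unwrapped = np.degrees(np.unwrap(np.radians(raw)))
    peaked = bool(np.median(contrasts) >= min_contrast)
    return PeakTrack(times=np.asarray(kymo.times, dtype=float),
                     angle=unwrapped, field=getattr(kymo, "field", "u"),
                     peaked=peaked)


def inhibitor_lag(u_track: PeakTrack, h_track: PeakTrack) -> float:
    """Mean signed angular offset of the inhibitor peak relative to the Rac
    peak, in the direction of rotation.

    Negative means the inhibitor trails behind the moving Rac zone (the
    configuration that pushes the zone forward).  Requires synchronized
    tracks; the rotation direction is taken from the Rac track's net
    motion (if the Rac peak is stationary the raw circular mean offset is
    returned, CCW-positive).
    """
    if len(u_track.times) != len(h_track.times) or \
            not np.allclose(u_track.times, h_track.times):
        raise ValueError("tracks must share the same time base")
    diff = wrap_angle(h_track.angle - u_track.angle)
    mean_off = float(np.degrees(np.angle(np.mean(
        np.exp(1j * np.radians(diff))))))
    net = u_track.angle[-1] - u_track.angle[0]
    direction = 1.0 if net >= 0 else -1.0
    return mean_off * direction


def rotation_velocity(track: PeakTrack) -> float:
    """Least-squares angular velocity (deg/s) of an unwrapped peak track."""
    t = track.times - track.times[0]
    if len(t) < 2:
        return 0.0
    return float(np.polyfit(t, track.angle, 1)[0])


def classify_rotation(headings: np.ndarray, times: np.ndarray,
                      window: float = 100.0,
                      threshold: float = ROTATION_THRESHOLD_DEG
                      ) -> List[str]:
    """Per-window rotation labels ("CCW", "CW", "none") from a heading
    series (compass deg; NaN allowed where the cell is still).

    The net winding of the unwrapped heading over each window is compared
    to ``threshold`` (scaled to the window length); a winding exactly at
    the threshold counts as "none".
    """
    times = np.asarray(times, dtype=float)
    headings = np.asarray(headings, dtype=float)
    ok = ~np.isnan(headings)
    labels = []
    t0 = times[0]
    while t0 + window <= times[-1] + 1e-9:
        sel = ok & (times >= t0) & (times <= t0 + window)
        if sel.sum() >= 5:
            h = np.degrees(np.unwrap(np.radians(headings[sel])))
            winding = h[-1] - h[0]
            scaled = threshold * window / 100.0
            if winding > scaled:
                labels.append("CCW")
            elif winding < -scaled:
                labels.append("CW")
            else:
                labels.append("none")
        else:
            labels.append("none")
        t0 += window
    return labels


def majority_rotation(headings: np.ndarray, times: np.ndarray,
                      t_start: float = 0.0, window: float = 100.0) -> str:
    """Dominant rotation label over the track segment from ``t_start``."""
    sel = times >= t_start
    labels = classify_rotation(headings[sel], times[sel], window=window)
    if not labels:
        return "none"
    counts = {lab: labels.count(lab) for lab in ("CCW", "CW", "none")}
    return max(counts, key=counts.get)


def front_rotation_label(track, t_start: float = 0.0,
                         threshold_deg_s: float = 0.15) -> str:
    """Rotation label ("CCW", "CW", "none") from the mean angular velocity
    of the unwrapped edge-front angle after ``t_start``.

    The front angle is the robust readout for rotation phenotypes: the
    centroid can stall transiently (e.g. mid-reversal) while the Rac zone
    keeps sweeping the edge."""
    times = np.asarray(track.times, dtype=float)
    fa = np.degrees(np.unwrap(np.radians(
        np.asarray(track.front_angle, dtype=float))))
    sel = times >= t_start
    if sel.sum() < 5:
        return "none"
    t, a = times[sel], fa[sel]
    vel = (a[-1] - a[0]) / (t[-1] - t[0])
    if vel > threshold_deg_s:
        return "CCW"
    if vel < -threshold_deg_s:
        return "CW"
    return "none"


def reorientation_time(times: np.ndarray, vy: np.ndarray,
                       t_reversal: float,
                       smooth: float = REORIENT_SMOOTH_S,
                       confirm_floor: float = 0.02,
                       confirm_window: float = 60.0) -> Optional[float]:
    """First time after ``t_reversal`` at which the smoothed vertical
    velocity crosses zero from positive to negative and the cell then
    genuinely moves down (the smoothed velocity reaches ``-confirm_floor``
    within ``confirm_window`` seconds).  None if no confirmed crossing
    occurs — a cell that keeps migrating up the stale gradient.  The
    confirmation step rejects zero grazes produced by lattice noise.
    A crossing exactly at a sample point returns that sample's time."""
    times = np.asarray(times, dtype=float)
    vy = np.asarray(vy, dtype=float)
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    k = max(1, int(round(smooth / dt)))
    kernel = np.ones(k) / k
    sm = np.convolve(vy, kernel, mode="same")
    for i in range(1, len(times)):
        if times[i] < t_reversal:
            continue
        if sm[i - 1] > 0 and sm[i] <= 0:
            sel = (times >= times[i]) & (times <= times[i] + confirm_window)
            if np.min(sm[sel]) <= -confirm_floor:
                return float(times[i])
    return None


def vertical_velocity(track, smooth: float = REORIENT_SMOOTH_S) -> np.ndarray:
    """Smoothed d(y)/dt of a centroid track (px/s, northward positive)."""
    times = np.asarray(track.times, dtype=float)
    y = np.asarray(track.y, dtype=float)
    vy = np.gradient(y, times)
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    k = max(1, int(round(smooth / dt)))
    return np.convolve(vy, np.ones(k) / k, mode="same")


def circular_alignment(headings_deg: Sequence[float]) -> Tuple[float, float]:
    """Circular mean direction (deg) and resultant length R in [0, 1]."""
    h = np.radians(np.asarray(headings_deg, dtype=float))
    if h.size == 0:
        raise ValueError("need at least one heading")
    z = np.mean(np.exp(1j * h))
    return float(np.degrees(np.angle(z))), float(np.abs(z))


# ---------------------------------------------------------------------------
# parameter interpretation
# ---------------------------------------------------------------------------

def parameter_interpretation(wp: Optional[ModelParams] = None,
                             wpi: Optional[ModelParams] = None,
                             wpi_pip3: Optional[ModelParams] = None) -> dict:
    """Derived quantities that interpret the fitted parameter tables.

    * inhibitor and Rac half-lives, ln(2)/rate (s);
    * basal-to-autocatalytic activation ratio k0/gamma (WP column);
    * fold excess of the WP basal inactivation rate over WPI's;
    * percent excess of total Rac in WP over WPI;
    * inferred inhibitor molecular-weight ratio from the diffusion ratio
      (D_u/D_h)^3, using the cube-root mass scaling of diffusion.
    """
    wp = wp or load_preset("wp")
    wpi = wpi or load_preset("wpi")
    wpi_pip3 = wpi_pip3 or load_preset("wpi_pip3")
    return {
        "inhibitor_half_life_s": math.log(2.0) / wpi.delta_h,
        "rac_half_life_s": math.log(2.0) / wpi.delta,
        "k0_over_gamma_wp": wp.k0 / wp.gamma,
        "delta_wp_over_wpi": wp.delta / wpi.delta,
        "total_rac_excess_percent": (wp.T - wpi.T) / wpi.T * 100.0,
        "inhibitor_mw_ratio": (wpi_pip3.D_u / wpi_pip3.D_h) ** 3,
    }


def interpretation_report(values: Optional[dict] = None) -> str:
    v = values or parameter_interpretation()
    lines = [
        "Parameter interpretation (packaged presets)",
        "-------------------------------------------",
        f"Inhibitor half-life  ln2/delta_h : {v['inhibitor_half_life_s']:8.1f} s",
        f"Active-Rac half-life ln2/delta   : {v['rac_half_life_s']:8.2f} s",
        f"Basal/autocatalytic  k0/gamma    : {v['k0_over_gamma_wp']:8.3f}   (WP)",
        f"Rac inactivation WP/WPI          : {v['delta_wp_over_wpi']:8.2f} x",
        f"Total Rac excess WP over WPI     : {v['total_rac_excess_percent']:8.1f} %",
        f"Inhibitor MW ratio (D_u/D_h)^3   : {v['inhibitor_mw_ratio']:8.1f} x Rac",
    ]
    return "\n".join(lines)
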