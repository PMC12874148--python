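"""Space-time optogenetic stimulus fields S(theta, t).

A protocol is a sum of components, each the product of a spatial profile
(uniform, or a periodically wrapped Gaussian patch) and a temporal profile
(step, double pulse, ramp, or constant), scaled by a dimensionless amplitude
in [0, 1].  The biochemical gain lives in the model's ``s`` (or ``s_p``)
rate, so amplitudes stay unitless.

Angles are degrees in the compass frame: 0 deg = north, counterclockwise
positive, wrapped to [-180, 180).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Tuple

import numpy as np

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
DEFAULT_WIDTH_DEG = 30.0  # Gaussian FWHM of the light patch


def wrap_angle(theta):
    """Wrap angle(s) in degrees to [-180, 180)."""
    return (np.asarray(theta, dtype=float) + 180.0) % 360.0 - 180.0


# ---------------------------------------------------------------------------
# spatial profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Uniform:
    """Whole-edge (global) stimulus."""

    def __call__(self, theta):
        return np.ones_like(np.asarray(theta, dtype=float))


@dataclass(frozen=True)
class Gaussian:
    """Gaussian light patch centered at ``center_deg`` with the given FWHM.

    The profile wraps around the ring, so a patch at +90 deg has a small but
    strictly positive tail at -90 deg.
    """

    center_deg: float
    width_deg: float = DEFAULT_WIDTH_DEG  # FWHM

    def __call__(self, theta):
        sigma = self.width_deg * FWHM_TO_SIGMA
        d = wrap_angle(np.asarray(theta, dtype=float) - self.center_deg)
        # wrapped sum over the nearest periodic images keeps the tail alive
        out = np.zeros_like(d)
        for k in (-360.0, 0.0, 360.0):
            out = out + np.exp(-0.5 * ((d + k) / sigma) ** 2)
        return out


# ---------------------------------------------------------------------------
# temporal profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Constant:
    def __call__(self, t):
        return np.ones_like(np.asarray(t, dtype=float))

    def breakpoints(self) -> Tuple[float, ...]:
        return ()


@dataclass(frozen=True)
class Step:
    """ON during [t_on, t_off)."""

    t_on: float
    t_off: float = math.inf

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return ((t >= self.t_on) & (t < self.t_off)).astype(float)

    def breakpoints(self) -> Tuple[float, ...]:
        out = (self.t_on,)
        if math.isfinite(self.t_off):
            out = out + (self.t_off,)
        return out


@dataclass(frozen=True)
class DoublePulse:
    """Two identical ON-OFF pulses of length ``pulse_len`` separated by an
    OFF interval ``gap``."""

    t_on: float
    pulse_len: float
    gap: float

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        a1, b1 = self.t_on, self.t_on + self.pulse_len
        a2 = b1 + self.gap
        b2 = a2 + self.pulse_len
        return (((t >= a1) & (t < b1)) | ((t >= a2) & (t < b2))).astype(float)

    def breakpoints(self) -> Tuple[float, ...]:
        a1, b1 = self.t_on, self.t_on + self.pulse_len
        a2 = b1 + self.gap
        return (a1, b1, a2, a2 + self.pulse_len)


@dataclass(frozen=True)
class Ramp:
    """Linear rise from 0 at ``t_on`` with slope ``rate`` (1/s), capped at
    ``S_max``."""

    t_on: float
    rate: float
    S_max: float = 1.0

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.clip((t - self.t_on) * self.rate, 0.0, self.S_max)

    def breakpoints(self) -> Tuple[float, ...]:
        if self.rate > 0:
            return (self.t_on, self.t_on + self.S_max / self.rate)
        return (self.t_on,)


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Component:
    spatial: Callable
    temporal: Callable
    amplitude: float = 1.0

    def evaluate(self, theta, t):
        return self.amplitude * self.spatial(theta) * self.temporal(t)


@dataclass(frozen=True)
class StimulusProtocol:
    """Sum of stimulus components; deterministic, non-negative, periodic."""

    components: Tuple[Component, ...]
    name: str = ""

    def evaluate(self, theta, t):
        theta = np.asarray(theta, dtype=float)
        out = np.zeros_like(theta)
        for c in self.components:
            out = out + c.evaluate(theta, t)
        return out if out.ndim else float(out)

    def breakpoints(self, t_end: float) -> np.ndarray:
        """Times in (0, t_end) where S is non-smooth in t."""
        pts = []
        for c in self.components:
            bp = getattr(c.temporal, "breakpoints", lambda: ())()
            pts.extend(b for b in bp if 0.0 < b < t_end)
        return np.unique(np.asarray(pts, dtype=float))


# ---------------------------------------------------------------------------
# named protocol builders
# ---------------------------------------------------------------------------

DEFAULT_PULSE_LEN = 30.0  # s, ON duration of one pulse
DEFAULT_T_ON = 60.0  # s, first light onset
DEFAULT_RAMP_DURATION = 200.0  # s to reach the step amplitude


def protocol_global_step(t_on: float = DEFAULT_T_ON, t_off: float = math.inf,
                         amplitude: float = 1.0) -> StimulusProtocol:
    return StimulusProtocol(
        (Component(Uniform(), Step(t_on, t_off), amplitude),), name="global_step")


def protocol_double_pulse(gap: float, t_on: float = DEFAULT_T_ON,
                          pulse_len: float = DEFAULT_PULSE_LEN,
                          amplitude: float = 1.0) -> StimulusProtocol:
    """Two global ON-OFF pulses separated by ``gap`` seconds of darkness."""
    if gap <= 0:
        raise ValueError("gap must be positive")
    return StimulusProtocol(
        (Component(Uniform(), DoublePulse(t_on, pulse_len, gap), amplitude),),
        name=f"double_pulse_{gap:g}")


def protocol_global_ramp(t_on: float = DEFAULT_T_ON,
                         duration: float = DEFAULT_RAMP_DURATION,
                         amplitude: float = 1.0,
                         t_off: float = math.inf) -> StimulusProtocol:
    """Gradual global rise to ``amplitude`` over ``duration`` seconds."""
    comp = Component(Uniform(), Ramp(t_on, amplitude / duration, amplitude), 1.0)
    comps = [comp]
    if math.isfinite(t_off):
        # subtract to switch the ramp off (kept non-negative by construction)
        comps = [Component(Uniform(),
                           _RampOff(t_on, amplitude / duration, amplitude, t_off), 1.0)]
    return StimulusProtocol(tuple(comps), name="ramp")


@dataclass(frozen=True)
class _RampOff:
    t_on: float
    rate: float
    S_max: float
    t_off: float

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        val = np.clip((t - self.t_on) * self.rate, 0.0, self.S_max)
        return np.where(t < self.t_off, val, 0.0)

    def breakpoints(self):
        return (self.t_on, self.t_on + self.S_max / self.rate, self.t_off)


def protocol_local(center_deg: float, t_on: float = 0.0,
                   t_off: float = math.inf, amplitude: float = 1.0,
                   width_deg: float = DEFAULT_WIDTH_DEG) -> StimulusProtocol:
    return StimulusProtocol(
        (Component(Gaussian(center_deg, width_deg), Step(t_on, t_off), amplitude),),
        name="local")


def protocol_rear_local(t_on: float = 100.0, t_off: float = 300.0,
                        amplitude: float = 1.0) -> StimulusProtocol:
    """Local patch at the cell rear (180 deg from a north-facing front)."""
    p = protocol_local(180.0, t_on, t_off, amplitude)
    return StimulusProtocol(p.components, name="rear_local")


def protocol_two_sided(t_on: float = 100.0, t_off: float = 300.0,
                       amplitude: float = 1.0) -> StimulusProtocol:
    """Competing local patches on the left (+90) and right (-90) sides."""
    return StimulusProtocol(
        (Component(Gaussian(90.0), Step(t_on, t_off), amplitude),
         Component(Gaussian(-90.0), Step(t_on, t_off), amplitude)),
        name="two_sided")


def protocol_competing(mode: str, t_second: float = 100.0,
                       amplitude: float = 1.0,
                       ramp_duration: float = DEFAULT_RAMP_DURATION) -> StimulusProtocol:
    """First stimulus constant at -90 deg from t = 0; a second at +90 deg
    arrives at ``t_second`` either abruptly (``step``) or gradually
    (``ramp``)."""
    first = Component(Gaussian(-90.0), Constant(), amplitude)
    if mode == "step":
        second = Component(Gaussian(90.0), Step(t_second), amplitude)
    elif mode == "ramp":
        second = Component(Gaussian(90.0),
                           Ramp(t_second, amplitude / ramp_duration, amplitude), 1.0)
    else:
        raise ValueError("mode must be 'step' or 'ramp'")
    return StimulusProtocol((first, second), name=f"competing_{mode}")


def protocol_local_to_global(t_local_on: float = 100.0, t_switch: float = 300.0,
                             side_deg: float = 90.0, amplitude: float = 1.0,
                             t_end: float = math.inf) -> StimulusProtocol:
    """Local patch at ``side_deg`` on [t_local_on, t_switch); global uniform
    light from ``t_switch``.  In motility runs the patch angle is re-aimed
    relative to the cell front by the driver."""
    if not t_local_on < t_switch:
        raise ValueError("t_local_on must precede t_switch")
    return StimulusProtocol(
        (Component(Gaussian(side_deg), Step(t_local_on, t_switch), amplitude),
         Component(Uniform(), Step(t_switch, t_end), amplitude)),
        name="local_to_global")


def protocol_local_then_off(t_on: float = 100.0, t_off: float = 300.0,
                            side_deg: float = 90.0,
                            amplitude: float = 1.0) -> StimulusProtocol:
    """Local patch that simply turns off at ``t_off`` (rotation-persistence
    protocol)."""
    return StimulusProtocol(
        (Component(Gaussian(side_deg), Step(t_on, t_off), amplitude),),
        name="local_then_off")


PRESETS = {
    "rear_local": protocol_rear_local,
    "two_sided": protocol_two_sided,
    "double_pulse_120": lambda: protocol_double_pulse(120.0),
    "double_pulse_60": lambda: protocol_double_pulse(60.0),
    "ramp": protocol_global_ramp,
    "local_to_global": protocol_local_to_global,
    "local_then_off": protocol_local_then_off,
    "global_step": protocol_global_step,
}


def get_preset(name: str, **kwargs) -> StimulusProtocol:
    try:
        builder = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol preset {name!r}; choose from {sorted(PRESETS)}")
    return builder(**kwargs) if kwargs else builder()


def stimulus_rate_of_change(kymo):
    """Temporal derivative of a stimulus kymograph (centered differences,
    one-sided at the ends).  Returns a new Kymograph-like object."""
    from .rd_solver import Kymograph

    times = np.asarray(kymo.times, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two time samples")
    dvals = np.gradient(kymo.values, times, axis=0)
    return Kymograph(times=times, theta=np.asarray(kymo.theta, dtype=float),
                     values=dvals, field=f"d{kymo.field}_dt")
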