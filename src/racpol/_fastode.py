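"""Numba-compiled fixed-step integrators used inside optimization loops.

These kernels duplicate the well-mixed kinetics of
:mod:`racpol.core_models` with a classical RK4 stepper at fixed dt so that
a differential-evolution objective costs microseconds instead of
milliseconds.  A test pins them against the adaptive reference integrator.

Parameter vector layout (``theta``), shared by WP and WPI (WP ignores the
inhibitor entries by ``has_h = False``):

    [T, k0, s, gamma, K, delta, k1, alpha, delta_h]
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_HILL = 2.0  # Hill coefficient, fixed


@njit(cache=True)
def rest_state_u(theta, has_h):
    """Lowest positive root of the unstimulated kinetics by scan+bisection."""
    T, k0, s, gamma, K, delta, k1, alpha, delta_h = theta
    n_scan = 512
    u_prev = 0.0
    g_prev = k0 * T  # g(0)
    u_root = -1.0
    for i in range(1, n_scan + 1):
        u = T * i / n_scan
        hill = gamma * u ** N_HILL / (K ** N_HILL + u ** N_HILL)
        dec = delta
        if has_h:
            dec += k1 * alpha * u / delta_h
        g = (k0 + hill) * (T - u) - dec * u
        if g_prev > 0.0 and g <= 0.0:
            lo, hi = u_prev, u
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                hillm = gamma * mid ** N_HILL / (K ** N_HILL + mid ** N_HILL)
                decm = delta
                if has_h:
                    decm += k1 * alpha * mid / delta_h
                gm = (k0 + hillm) * (T - mid) - decm * mid
                if gm > 0.0:
                    lo = mid
                else:
                    hi = mid
            u_root = 0.5 * (lo + hi)
            break
        u_prev, g_prev = u, g
    return u_root


@njit(cache=True)
def integrate_forced(theta, has_h, t_samples, forcing, dt):
    """Integrate the well-mixed model driven by a piecewise-linear forcing
    trace (replacing S in the ``s*S`` activation term); returns active Rac
    in fold-change units at ``t_samples``.

    ``t_samples``/``forcing`` must be uniformly spaced from t = 0.
    """
    T, k0, s, gamma, K, delta, k1, alpha, delta_h = theta
    u0 = rest_state_u(theta, has_h)
    out = np.empty(len(t_samples))
    if u0 <= 0.0:
        out[:] = np.nan
        return out
    h0 = alpha * u0 / delta_h if has_h else 0.0
    dt_samp = t_samples[1] - t_samples[0]
    u, v, h = u0, T - u0, h0
    out[0] = 1.0
    n_sub = max(1, int(round(dt_samp / dt)))
    dts = dt_samp / n_sub
    nf = len(forcing)
    for i in range(1, len(t_samples)):
        t0 = t_samples[i - 1]
        for k in range(n_sub):
            ta = t0 + k * dts
            # linear interpolation of forcing at RK4 stage times
            du_acc = 0.0
            dh_acc = 0.0
            du_s = 0.0
            dh_s = 0.0
            for stage in range(4):
                if stage == 0:
                    ts = ta
                    us, vs, hs = u, v, h
                elif stage == 1:
                    ts = ta + 0.5 * dts
                    us, vs, hs = u + 0.5 * dts * du_s, v - 0.5 * dts * du_s, h + 0.5 * dts * dh_s
                elif stage == 2:
                    ts = ta + 0.5 * dts
                    us, vs, hs = u + 0.5 * dts * du_s, v - 0.5 * dts * du_s, h + 0.5 * dts * dh_s
                else:
                    ts = ta + dts
                    us, vs, hs = u + dts * du_s, v - dts * du_s, h + dts * dh_s
                # forcing value at ts
                x = ts / dt_samp
                j = int(x)
                if j >= nf - 1:
                    F = forcing[nf - 1]
                else:
                    w = x - j
                    F = forcing[j] * (1.0 - w) + forcing[j + 1] * w
                if F < 0.0:
                    F = 0.0
                if us < 0.0:
                    us = 0.0
                hill = gamma * us ** N_HILL / (K ** N_HILL + us ** N_HILL)
                act = k0 + hill + s * F
                dec = delta + (k1 * hs if has_h else 0.0)
                du_s = act * vs - dec * us
                dh_s = (alpha * us - delta_h * hs) if has_h else 0.0
                if stage == 0 or stage == 3:
                    du_acc += du_s
                    dh_acc += dh_s
                else:
                    du_acc += 2.0 * du_s
                    dh_acc += 2.0 * dh_s
            u += dts / 6.0 * du_acc
            v -= dts / 6.0 * du_acc
            h += dts / 6.0 * dh_acc
        out[i] = u / u0
    return out


@njit(cache=True)
def rss_forced(theta, has_h, t_samples, forcing, rac, dt):
    """Sum of squared residuals between the model readout and ``rac``."""
    pred = integrate_forced(theta, has_h, t_samples, forcing, dt)
    rss = 0.0
    for i in range(len(rac)):
        if np.isnan(pred[i]):
            return 1e12
        d = pred[i] - rac[i]
        rss += d * d
    return rss
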