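import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from racpol import (
    ModelConfigError,
    ModelParams,
    Variant,
    WellMixedState,
    compute_rest_state,
    hill_activation,
    integrate_well_mixed,
    integrate_well_mixed_rk4,
    load_preset,
    normalize_to_baseline,
    protocol_double_pulse,
    protocol_global_step,
    reaction_terms,
)


# ---------------------------------------------------------------------------
# parameters / presets
# ---------------------------------------------------------------------------

def test_presets_carry_fitted_table_values(wp, wpi):
    assert (wp.T, wp.k0, wp.s, wp.gamma, wp.K, wp.delta, wp.n) == \
        (9.78, 0.035, 0.12, 1.31, 2.75, 2.70, 2)
    assert (wpi.T, wpi.k0, wpi.s, wpi.gamma, wpi.K, wpi.delta) == \
        (7.31, 0.028, 0.059, 1.38, 2.93, 0.721)
    assert (wpi.k1, wpi.alpha, wpi.delta_h) == (0.372, 6.8e-3, 4.0e-3)
    assert (wpi.D_u, wpi.D_v, wpi.D_h) == (1.0, 3.37, 0.14)


def test_pip3_preset_diffusion_ratios(wpi_pip3):
    assert (wpi_pip3.D_u, wpi_pip3.D_v, wpi_pip3.D_h) == (1.0, 6.40, 0.47)
    assert wpi_pip3.k_p > 0 and wpi_pip3.s_p > 0 and wpi_pip3.delta_p > 0


def test_variant_irrelevant_fields_rejected(wp):
    with pytest.raises(ModelConfigError):
        wp.with_updates(k1=0.1)  # WP has no inhibitor coupling
    with pytest.raises(ModelConfigError):
        ModelParams(variant="wpi", T=1, k0=0.1, s=0.1, gamma=1, K=1,
                    delta=1)  # missing inhibitor parameters


def test_invalid_parameters_rejected():
    with pytest.raises(ModelConfigError):
        ModelParams(variant="wp", T=0.0, k0=0.1, s=0.1, gamma=1, K=1, delta=1)
    with pytest.raises(ModelConfigError):
        ModelParams(variant="wp", T=1, k0=-0.1, s=0.1, gamma=1, K=1, delta=1)
    with pytest.raises(ModelConfigError):
        ModelParams(variant="wp", T=1, k0=0.1, s=0.1, gamma=1, K=1, delta=1,
                    n=0)


# ---------------------------------------------------------------------------
# Hill autocatalysis
# ---------------------------------------------------------------------------

def test_hill_half_max_gives_gamma_over_two(wpi):
    assert hill_activation(wpi.K, wpi) == pytest.approx(wpi.gamma / 2)


def test_hill_zero_and_saturation(wp):
    assert hill_activation(0.0, wp) == 0.0
    assert hill_activation(1e6 * wp.K, wp) == pytest.approx(wp.gamma,
                                                            rel=1e-6)


def test_hill_rejects_negative_activity(wp):
    with pytest.raises(ValueError):
        hill_activation(-0.1, wp)


@settings(deadline=None, max_examples=50)
@given(u1=st.floats(0, 50), u2=st.floats(0, 50))
def test_hill_monotone_and_bounded(u1, u2):
    wp = load_preset("wp")
    lo, hi = sorted((u1, u2))
    a, b = hill_activation(lo, wp), hill_activation(hi, wp)
    assert 0 <= a <= b < wp.gamma + 1e-12


# ---------------------------------------------------------------------------
# reaction terms
# ---------------------------------------------------------------------------

@settings(deadline=None, max_examples=50)
@given(u=st.floats(0, 10), v=st.floats(0, 10), h=st.floats(0, 5),
       S=st.floats(0, 2))
def test_mass_conservation_by_construction(u, v, h, S):
    """Active and inactive Rac have exactly opposite kinetics."""
    for name in ("wp", "wpi"):
        prm = load_preset(name)
        st_ = WellMixedState(u=u, v=v, h=h)
        du, dv, dh, dp = reaction_terms(st_, S, prm)
        assert dv == -du  # bit-identical


def test_wpi_zero_state_rates(wpi):
    state = WellMixedState(u=0.0, v=wpi.T, h=0.0)
    du, dv, dh, dp = reaction_terms(state, 0.0, wpi)
    assert du == pytest.approx(wpi.k0 * wpi.T)
    assert dh == 0.0 and dp == 0.0


def test_rest_state_is_equilibrium(wp, wpi, wpi_pip3):
    for prm in (wp, wpi, wpi_pip3):
        rest = compute_rest_state(prm)
        rates = reaction_terms(rest, 0.0, prm)
        assert max(abs(r) for r in rates) < 1e-10


def test_rest_state_matches_bisection_oracle(wp, wpi):
    """Independent oracle: dense scan + interval bisection of the
    unstimulated net-activation function g(u)."""
    def oracle(prm):
        def g(u):
            h = prm.alpha * u / prm.delta_h if prm.has_inhibitor else 0.0
            act = prm.k0 + prm.gamma * u ** prm.n / (prm.K ** prm.n + u ** prm.n)
            dec = prm.delta + (prm.k1 * h if prm.has_inhibitor else 0.0)
            return act * (prm.T - u) - dec * u

        us = np.linspace(0.0, prm.T, 200001)
        gs = g(us)
        i = int(np.nonzero((gs[:-1] > 0) & (gs[1:] <= 0))[0][0])
        lo, hi = us[i], us[i + 1]
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if g(mid) > 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    assert compute_rest_state(wp).u == pytest.approx(oracle(wp), abs=1e-10)
    assert compute_rest_state(wpi).u == pytest.approx(oracle(wpi), abs=1e-10)


def test_rest_state_positive_whenever_k0_positive(wp):
    rest = compute_rest_state(wp)
    assert rest.u > 0
    assert rest.v == pytest.approx(wp.T - rest.u)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_normalize_to_baseline(wpi):
    rest = compute_rest_state(wpi)
    const = np.full(10, rest.u)
    assert normalize_to_baseline(const, wpi) == pytest.approx(np.ones(10))
    assert normalize_to_baseline(2 * rest.u, wpi) == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# well-mixed integration
# ---------------------------------------------------------------------------

def test_rest_state_is_fixed_point_of_integration(wpi):
    traj = integrate_well_mixed(wpi, protocol=None, t_end=1000.0, dt_out=50.0)
    assert np.all(np.abs(traj.u - 1.0) < 1e-8)
    assert np.all(np.abs(traj.u * traj.u_rest + traj.v - wpi.T)
                  < 1e-6 * wpi.T)


def test_wpi_step_overshoots_then_adapts(wpi):
    """Abrupt ON: rise, overshoot, decay back toward (or below) baseline."""
    traj = integrate_well_mixed(wpi, protocol_global_step(t_on=60.0),
                                t_end=480.0, dt_out=1.0)
    peak_i = int(np.argmax(traj.u))
    assert traj.u[peak_i] > 2.0
    assert 60.0 < traj.times[peak_i] < 120.0
    assert traj.u[-1] < 0.6 * traj.u[peak_i]  # pronounced decay after peak


def test_wp_step_rises_monotonically_no_overshoot(wp):
    traj = integrate_well_mixed(wp, protocol_global_step(t_on=60.0),
                                t_end=480.0, dt_out=1.0)
    after_on = traj.u[traj.times >= 60.0]
    assert np.all(np.diff(after_on) > -1e-6)
    assert traj.u[-1] == pytest.approx(after_on.max(), rel=1e-3)


def test_wpi_rate_sensing_step_fires_ramp_does_not(wpi):
    """At matched final amplitude the abrupt step fires a large transient
    spike while a slow ramp gives only a mild graded rise."""
    from racpol.core_models import experiment_step_vs_ramp

    res = experiment_step_vs_ramp(wpi)
    assert res["step_overshoot"] > 1.0  # spike then adaptation
    assert res["ramp_overshoot"] < 0.2  # quasi-static tracking
    assert res["step"].u.max() > 3 * res["ramp"].u.max()


def test_double_pulse_adaptation_ordering(wpi):
    """Second peak smaller than first; deficit larger for the shorter gap;
    undershoot below baseline between pulses (inhibitor-specific traits)."""
    results = {}
    for gap in (120.0, 60.0):
        traj = integrate_well_mixed(wpi, protocol_double_pulse(gap),
                                    t_end=480.0, dt_out=1.0)
        t, u = traj.times, traj.u
        t2_on = 90.0 + gap
        p1 = u[(t >= 60.0) & (t < t2_on)].max()
        p2 = u[t >= t2_on].max()
        under = u[(t >= 90.0) & (t < t2_on)].min()
        results[gap] = (p1, p2, under)
    for gap, (p1, p2, under) in results.items():
        assert p2 < p1, f"no adaptation at gap {gap}"
        assert under < 1.0, f"no undershoot at gap {gap}"
    deficit_60 = results[60.0][0] - results[60.0][1]
    deficit_120 = results[120.0][0] - results[120.0][1]
    assert deficit_60 > deficit_120


def test_wp_shows_no_adaptation_features(wp):
    traj = integrate_well_mixed(wp, protocol_double_pulse(120.0),
                                t_end=480.0, dt_out=1.0)
    t, u = traj.times, traj.u
    p1 = u[(t >= 60.0) & (t < 210.0)].max()
    p2 = u[t >= 210.0].max()
    under = u[(t >= 90.0) & (t < 210.0)].min()
    assert p2 == pytest.approx(p1, rel=1e-3)  # equal peaks
    assert under >= 1.0 - 1e-6  # never below baseline


def test_conservation_through_stimulated_run(wp, wpi):
    for prm in (wp, wpi):
        traj = integrate_well_mixed(prm, protocol_double_pulse(60.0),
                                    t_end=480.0, dt_out=5.0)
        total = traj.u * traj.u_rest + traj.v
        assert np.all(np.abs(total - prm.T) < 1e-6 * prm.T)


def test_adaptive_integrator_matches_rk4_reference(wpi):
    """Fixed-step RK4 at dt = 1 ms agrees with the adaptive path to 1e-4
    relative on the 480 s double-pulse run."""
    prot = protocol_double_pulse(120.0)
    # sample between (not at) the stimulus switch times, where the two
    # integrators' switch conventions differ by one micro-step
    ref = integrate_well_mixed_rk4(wpi, prot, t_end=480.0, dt=1e-3,
                                   dt_out=7.0)
    traj = integrate_well_mixed(wpi, prot, t_end=480.0, dt_out=7.0)
    rel = np.abs(traj.u - ref.u) / np.abs(ref.u)
    assert rel.max() < 1e-4


def test_forcing_trace_validation(wpi):
    from racpol import CellTrace

    times = np.arange(0.0, 101.0, 5.0)
    short = CellTrace("c", times, np.zeros_like(times), np.ones_like(times))
    with pytest.raises(ValueError):
        integrate_well_mixed(wpi, t_end=480.0, pip3_forcing=short)
    neg = CellTrace("c", times, np.full_like(times, -1.0),
                    np.ones_like(times))
    with pytest.raises(ValueError):
        integrate_well_mixed(wpi, t_end=100.0, pip3_forcing=neg)


def test_pip3_forcing_rejected_for_pip3_variant(wpi_pip3):
    from racpol import CellTrace

    times = np.arange(0.0, 481.0, 5.0)
    tr = CellTrace("c", times, np.zeros_like(times), np.ones_like(times))
    with pytest.raises(ModelConfigError):
        integrate_well_mixed(wpi_pip3, t_end=480.0, pip3_forcing=tr)
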