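"""Maturation and trafficking kinetics against independent oracles.

Closed forms are cross-checked by numerical quadrature of the cohort
integral, Monte-Carlo over exponential age mixtures, and long-horizon ODE
integration.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import tftimer as tt
from tftimer.kinetics import KineticsError, RatioOutOfRange

from conftest import equal_rate_pair

LN2 = np.log(2.0)


def cohort_quadrature(t, D, m):
    """Independent oracle: integrate 1 - e^{-m(t-s)} over synthesis times."""
    if t <= 0:
        return 0.0
    val, _ = quad(lambda s: 1.0 - np.exp(-m * (t - s)), 0.0, min(t, D))
    return val / D


class TestPulseMaturedFraction:
    @pytest.mark.parametrize(
        "t,D,m,expected",
        [
            (0.0, 1.0, LN2 / 3, 0.0),
            (2.0, 1.0, LN2 / 3, 0.2912),   # frozen from the quadrature oracle
            (2.0, 1.0, LN2 / 6, 0.1585),
        ],
    )
    def test_frozen_values(self, t, D, m, expected):
        assert tt.pulse_matured_fraction(t, D, m) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("t", [0.3, 0.9, 1.0, 1.7, 4.2, 11.0])
    @pytest.mark.parametrize("m", [LN2 / 3, LN2 / 6, 0.9])
    def test_matches_quadrature(self, t, m):
        D = 1.0
        assert tt.pulse_matured_fraction(t, D, m) == pytest.approx(
            cohort_quadrature(t, D, m), abs=1e-9
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        m=st.floats(0.02, 3.0),
        D=st.floats(0.1, 4.0),
    )
    def test_monotone_bounded(self, m, D):
        # stay below the age where 1 - f reaches float round-off
        t = np.linspace(0.0, min(30.0, D + 20.0 / m), 200)
        f = tt.pulse_matured_fraction(t, D, m)
        assert f[0] == 0.0
        assert np.all(np.diff(f) > 0)
        assert np.all((f >= 0) & (f < 1))
        assert tt.pulse_matured_fraction(D + 50.0 / m, D, m) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_parameter_domain_errors(self):
        with pytest.raises(KineticsError):
            tt.pulse_matured_fraction(1.0, -1.0, 0.2)
        with pytest.raises(KineticsError):
            tt.pulse_matured_fraction(1.0, 1.0, 0.0)


class TestPulseRatioCurve:
    def test_small_age_limit_is_rate_ratio(self, pair):
        c = tt.pulse_ratio_curve(pair, times=np.array([1e-4, 1.0]))
        assert c.ratios[0] == pytest.approx(pair.m_slow / pair.m_fast, abs=1e-4)

    @pytest.mark.parametrize(
        "age,expected",
        [(2.0, 0.544), (4.5, 0.614), (8.0, 0.704)],  # quadrature-oracle ratios
    )
    def test_frozen_ratios(self, curve, age, expected):
        assert curve.ratio_at(age) == pytest.approx(expected, abs=1e-3)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        half_fast=st.floats(0.5, 8.0),
        factor=st.floats(1.2, 6.0),
        D=st.floats(0.25, 3.0),
    )
    def test_strictly_increasing_and_bounded(self, half_fast, factor, D):
        p = tt.FluorophorePair.from_half_times(half_fast, half_fast * factor)
        c = tt.pulse_ratio_curve(p, pulse_duration=D)
        assert np.all(np.diff(c.ratios) > 0)
        assert np.all(c.ratios > p.m_slow / p.m_fast)
        assert np.all(c.ratios < 1.0)

    def test_equal_rates_give_flat_unit_ratio(self):
        # degenerate timer: identical maturation carries no age information
        p = equal_rate_pair()
        t = np.linspace(0.25, 12.0, 48)
        f = tt.pulse_matured_fraction(t, 1.0, p.m_fast)
        s = tt.pulse_matured_fraction(t, 1.0, p.m_slow)
        assert np.allclose(s / f, 1.0, atol=1e-12)
        assert tt.steady_state_ratio(0.4, p) == pytest.approx(1.0, abs=1e-12)

    def test_empty_grid_rejected(self, pair):
        with pytest.raises(KineticsError):
            tt.pulse_ratio_curve(pair, times=np.array([]))


class TestSteadyStateRatio:
    def test_limits(self, pair):
        assert tt.steady_state_ratio(0.0, pair) == 1.0
        assert tt.steady_state_ratio(1e9, pair) == pytest.approx(
            pair.m_slow / pair.m_fast, rel=1e-6
        )

    def test_against_monte_carlo_age_mixture(self, pair):
        # independent oracle: matured fractions averaged over exponential ages
        k = 1.0 / 3.0
        rng = np.random.default_rng(42)
        ages = rng.exponential(1.0 / k, size=400_000)
        mc = np.mean(1 - np.exp(-pair.m_slow * ages)) / np.mean(
            1 - np.exp(-pair.m_fast * ages)
        )
        closed = tt.steady_state_ratio(k, pair)
        assert closed == pytest.approx(0.6287, abs=5e-4)  # frozen
        assert closed == pytest.approx(mc, rel=5e-3)

    def test_strictly_decreasing_in_k(self, pair):
        k = np.linspace(0.0, 5.0, 200)
        r = np.array([tt.steady_state_ratio(v, pair) for v in k])
        assert np.all(np.diff(r) < 0)

    def test_negative_k_rejected(self, pair):
        with pytest.raises(KineticsError):
            tt.steady_state_ratio(-0.1, pair)


class TestInvertSteadyStateRatio:
    def test_frozen_example(self, pair):
        k = tt.invert_steady_state_ratio(0.6287, pair)
        assert k == pytest.approx(1.0 / 3.0, rel=2e-3)
        assert 1.0 / k == pytest.approx(3.0, rel=2e-3)

    def test_boundaries_raise(self, pair):
        with pytest.raises(RatioOutOfRange):
            tt.invert_steady_state_ratio(1.0, pair)
        with pytest.raises(RatioOutOfRange):
            tt.invert_steady_state_ratio(pair.m_slow / pair.m_fast, pair)

    def test_round_trip_over_log_spaced_rates(self, pair):
        for k in np.logspace(-3, 2, 50):
            r = tt.steady_state_ratio(k, pair)
            assert tt.invert_steady_state_ratio(r, pair) == pytest.approx(
                k, rel=1e-9, abs=1e-12
            )


class TestTrafficking:
    def test_zero_synthesis_stays_empty(self, pair):
        p = tt.TraffickingParams(sigma=0.0, k_exit=0.3, k_deg=0.4)
        traj = tt.simulate_trafficking(p, pair, np.linspace(0, 10, 11))
        for arr in list(traj.totals.values()) + list(traj.matured.values()):
            assert np.allclose(arr, 0.0, atol=1e-12)

    def test_steady_state_closed_form_example(self, pair):
        p = tt.TraffickingParams(sigma=1.0, k_exit=0.25, k_deg=0.5)
        ss = tt.steady_state_pools(p, pair)
        assert ss.B == pytest.approx(4.0)
        assert ss.B_mat["fast"] == pytest.approx(1.921, abs=1e-3)
        assert ss.E == pytest.approx(2.0)
        assert ss.E_mat["fast"] == pytest.approx(1.289, abs=1e-3)

    def test_ode_converges_to_closed_form(self, pair):
        p = tt.TraffickingParams(sigma=1.0, k_exit=0.25, k_deg=0.5)
        traj = tt.simulate_trafficking(p, pair, np.array([0.0, 300.0]))
        ss = tt.steady_state_pools(p, pair)
        assert traj.totals["B"][-1] == pytest.approx(ss.B, rel=1e-6)
        assert traj.matured[("B", "fast")][-1] == pytest.approx(
            ss.B_mat["fast"], rel=1e-6
        )
        assert traj.matured[("E", "slow")][-1] == pytest.approx(
            ss.E_mat["slow"], rel=1e-6
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        sigma=st.floats(0.1, 5.0),
        k_exit=st.floats(0.05, 3.0),
        k_deg=st.floats(0.05, 3.0),
    )
    def test_random_params_match_closed_form(self, pair, sigma, k_exit, k_deg):
        p = tt.TraffickingParams(sigma=sigma, k_exit=k_exit, k_deg=k_deg)
        horizon = 40.0 / min(k_exit, k_deg, pair.m_slow)
        traj = tt.simulate_trafficking(p, pair, np.array([0.0, horizon]))
        ss = tt.steady_state_pools(p, pair)
        final = traj.state_at(-1)
        assert final.B == pytest.approx(ss.B, rel=1e-6, abs=1e-9)
        for f in ("fast", "slow"):
            assert final.B_mat[f] == pytest.approx(ss.B_mat[f], rel=1e-6, abs=1e-9)
            assert final.E_mat[f] == pytest.approx(ss.E_mat[f], rel=1e-6, abs=1e-9)

    def test_basolateral_matured_fraction_closed_form(self, pair):
        for k_exit in (0.1, 0.5, 2.0):
            p = tt.TraffickingParams(sigma=2.0, k_exit=k_exit, k_deg=0.7)
            ss = tt.steady_state_pools(p, pair)
            m = pair.m_fast
            assert ss.B_mat["fast"] / ss.B == pytest.approx(m / (m + k_exit), rel=1e-12)

    def test_mass_balance(self, pair):
        p = tt.TraffickingParams(sigma=1.3, k_exit=0.4, k_deg=0.6)
        times = np.linspace(0.0, 24.0, 49)
        traj = tt.simulate_trafficking(p, pair, times)
        present = traj.totals["B"] + traj.totals["E"]
        synthesized = p.sigma * times
        assert np.allclose(synthesized - traj.degraded, present, rtol=1e-7, atol=1e-7)

    def test_trajectory_invariants(self, pair):
        p = tt.TraffickingParams(sigma=1.0, k_exit=0.3, k_deg=0.5)
        traj = tt.simulate_trafficking(p, pair, np.linspace(0, 30, 61))
        for pool in ("B", "E"):
            total = traj.totals[pool]
            assert np.all(total >= 0)
            for f in ("fast", "slow"):
                mat = traj.matured[(pool, f)]
                assert np.all(mat >= -1e-12)
                assert np.all(mat <= total + 1e-9)
        assert traj.state_at(0).B == 0.0

    def test_grid_validation(self, pair):
        p = tt.TraffickingParams(sigma=1.0, k_exit=0.3, k_deg=0.5)
        with pytest.raises(KineticsError):
            tt.simulate_trafficking(p, pair, np.array([]))
        with pytest.raises(KineticsError):
            tt.simulate_trafficking(p, pair, np.array([2.0, 1.0]))


class TestDomainTypes:
    def test_fluorophore_pair_validation(self):
        with pytest.raises(KineticsError):
            tt.FluorophorePair(m_fast=0.1, m_slow=0.2)
        with pytest.raises(KineticsError):
            tt.FluorophorePair(m_fast=0.2, m_slow=0.1, q_fast_acidic=1.5)
        p = tt.FluorophorePair.from_half_times(3.0, 6.0)
        assert p.half_fast == pytest.approx(3.0)
        assert p.half_slow == pytest.approx(6.0)
        n = p.neutralized()
        assert n.q_fast_acidic == 1.0 and n.q_slow_acidic == 1.0

    def test_trafficking_params_validation(self):
        with pytest.raises(KineticsError):
            tt.TraffickingParams(sigma=-1.0, k_exit=0.5, k_deg=0.5)
        with pytest.raises(KineticsError):
            tt.TraffickingParams(sigma=1.0, k_exit=0.0, k_deg=0.5)
        p = tt.TraffickingParams.from_residence_time(4.0)
        assert p.residence_time == pytest.approx(4.0)

    def test_curve_inversion_round_trip(self, curve):
        for age in np.linspace(0.3, 11.9, 25):
            r = curve.ratio_at(age)
            assert curve.age_at(r) == pytest.approx(age, abs=1e-5)
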