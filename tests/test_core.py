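"""Closed forms of the unconstrained and delayed surge chains."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surgekinetics import (
    DegenerateRatesError,
    DelayedRateSet,
    RateSet,
    delayed_model_at,
    max_admitted_fraction,
    simple_model_at,
    time_of_max_admitted,
    time_of_max_surge_delayed,
)
from surgekinetics.oracle import delayed_ode, integrate, simple_ode

rates_st = st.builds(
    RateSet,
    ka=st.floats(0.05, 2.0),
    kd=st.floats(0.05, 3.0),
)


class TestSimpleModel:
    def test_initial_condition(self):
        assert simple_model_at(0.0, RateSet(0.3, 1.7)) == (1.0, 0.0, 0.0)

    def test_everyone_discharged_at_long_times(self):
        rates = RateSet(0.158, 1.151)
        state = simple_model_at(1e3 / rates.ka, rates)
        assert state.Nd == pytest.approx(1.0, abs=1e-6)
        assert state.Ns == pytest.approx(0.0, abs=1e-6)
        assert state.Na == pytest.approx(0.0, abs=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            simple_model_at(-0.1, RateSet(0.3, 1.7))

    def test_matches_numeric_integration(self):
        rates = RateSet(0.158, 1.151)
        t_grid = np.linspace(0.0, 8.0, 17)
        numeric = integrate(simple_ode(rates), t_grid, step=1e-3)
        closed = np.array([simple_model_at(t, rates) for t in t_grid])
        np.testing.assert_allclose(closed, numeric, atol=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(rates=rates_st, t=st.floats(0.0, 100.0))
    def test_conservation_and_bounds(self, rates, t):
        state = simple_model_at(t, rates)
        assert math.isclose(sum(state), 1.0, abs_tol=1e-9)
        assert all(-1e-12 <= x <= 1.0 + 1e-12 for x in state)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(rates=rates_st)
    def test_surge_decreases_and_discharges_increase(self, rates):
        grid = np.linspace(0.0, 30.0, 301)
        states = np.array([simple_model_at(t, rates) for t in grid])
        assert np.all(np.diff(states[:, 0]) <= 1e-12)
        assert np.all(np.diff(states[:, 2]) >= -1e-12)

    def test_degenerate_rates_continuous_limit(self):
        t = 1.7
        exact = simple_model_at(t, RateSet(1.0, 1.0))
        near = simple_model_at(t, RateSet(1.0, 1.0 + 1e-7))
        assert np.allclose(exact, near, atol=1e-6)
        assert exact.Na == pytest.approx(1.0 * t * math.exp(-t))


class TestAdmittedMaximum:
    def test_historical_rates_peak_at_two_days(self, fitted_rates):
        assert time_of_max_admitted(fitted_rates) == pytest.approx(2.0, abs=1e-9)

    def test_equal_rates_limit(self):
        assert time_of_max_admitted(RateSet(1.0, 1.0)) == pytest.approx(1.0)
        assert max_admitted_fraction(RateSet(1.0, 1.0)) == pytest.approx(math.exp(-1))

    @pytest.mark.parametrize("ka,kd", [(0.5, 2.0), (0.158, 1.151), (1.4, 0.3)])
    def test_argmax_agrees_with_grid_search(self, ka, kd):
        rates = RateSet(ka, kd)
        grid = np.linspace(1e-4, 30.0, 60_001)
        na = np.array([simple_model_at(t, rates).Na for t in grid])
        assert time_of_max_admitted(rates) == pytest.approx(grid[np.argmax(na)], abs=1e-3)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(rates=rates_st)
    def test_peak_fraction_consistent_with_model(self, rates):
        t_star = time_of_max_admitted(rates)
        assert max_admitted_fraction(rates) == pytest.approx(
            simple_model_at(t_star, rates).Na, abs=1e-10)


class TestDelayedModel:
    def test_initial_condition(self):
        rates = DelayedRateSet(ks=0.5, ka=0.2, kd=1.0)
        assert delayed_model_at(0.0, rates) == (1.0, 0.0, 0.0, 0.0)

    def test_fast_exposure_approaches_instantaneous_surge(self):
        slow = RateSet(0.2, 1.0)
        fast = DelayedRateSet(ks=1e3 * 0.2, ka=0.2, kd=1.0)
        for t in (1.0, 3.0, 8.0):
            d = delayed_model_at(t, fast)
            s = simple_model_at(t, slow)
            assert d.Ns == pytest.approx(s.Ns, abs=1e-2)
            assert d.Na == pytest.approx(s.Na, abs=1e-2)
            assert d.Nd == pytest.approx(s.Nd, abs=1e-2)

    def test_matches_numeric_integration(self):
        rates = DelayedRateSet(ks=0.5, ka=0.2, kd=1.0)
        t_grid = np.linspace(0.0, 12.0, 25)
        numeric = integrate(delayed_ode(rates), t_grid, step=1e-3)
        closed = np.array([delayed_model_at(t, rates) for t in t_grid])
        np.testing.assert_allclose(closed, numeric, atol=1e-6)

    def test_equal_rates_rejected(self):
        with pytest.raises(DegenerateRatesError):
            delayed_model_at(1.0, DelayedRateSet(ks=0.2, ka=0.2, kd=1.0))

    def test_surge_peak_time(self):
        rates = DelayedRateSet(ks=0.5, ka=0.2, kd=1.0)
        t_star = time_of_max_surge_delayed(rates)
        assert t_star == pytest.approx(math.log(0.2 / 0.5) / (0.2 - 0.5))
        grid = np.linspace(1e-4, 30.0, 30_001)
        ns = np.array([delayed_model_at(t, rates).Ns for t in grid])
        assert t_star == pytest.approx(grid[np.argmax(ns)], abs=2e-3)

    def test_surge_peak_argmax_for_random_rates(self, rng):
        for _ in range(20):
            ks, ka = rng.uniform(0.1, 2.0, size=2)
            if abs(ks - ka) < 1e-3:
                continue
            kd = rng.uniform(0.1, 2.0)
            while min(abs(kd - ks), abs(kd - ka)) < 1e-3:
                kd = rng.uniform(0.1, 2.0)
            rates = DelayedRateSet(ks=ks, ka=ka, kd=kd)
            t_star = time_of_max_surge_delayed(rates)
            grid = np.linspace(1e-4, 4.0 * t_star, 20_001)
            ns = np.array([delayed_model_at(t, rates).Ns for t in grid])
            dx = grid[1] - grid[0]
            assert t_star == pytest.approx(grid[np.argmax(ns)], abs=2 * dx)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(t=st.floats(0.0, 100.0))
    def test_conservation(self, t):
        state = delayed_model_at(t, DelayedRateSet(ks=0.5, ka=0.2, kd=1.0))
        assert math.isclose(sum(state), 1.0, abs_tol=1e-9)


class TestRateSetValidation:
    def test_positive_rates_required(self):
        with pytest.raises(ValueError):
            RateSet(ka=-0.1, kd=1.0)
        with pytest.raises(ValueError):
            RateSet(ka=0.1, kd=0.0)

    def test_throughput_not_faster_than_discharge(self):
        with pytest.raises(ValueError, match="k_prime"):
            RateSet(ka=0.1, kd=0.5, k_prime=0.6)

    def test_degeneracy_flag(self):
        assert RateSet(ka=1.0, kd=1.0 + 1e-12).is_degenerate
        assert not RateSet(ka=1.0, kd=1.1).is_degenerate
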