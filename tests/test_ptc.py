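"""Two-center model: region-I forms, boundary constants, breakpoints, t99."""

import numpy as np
import pytest
from scipy.optimize import brentq

from surgekinetics import (
    PediatricFasterError,
    PTCRateSet,
    RateSet,
    adult_cohort_at,
    capacity_model_at,
    capacity_t99,
    ptc_boundaries,
    ptc_model_at,
    ptc_rates_from_adult,
    ptc_region1_at,
    ptc_t2,
    ptc_t99,
    ptc_timescales,
    simple_model_at,
)
from surgekinetics.oracle import integrate, ptc_ode


def random_ptc_rates(rng):
    """Valid adult-faster two-center rates: PTC scaled below the adult."""
    ka = rng.uniform(0.08, 0.8)
    kd = ka * rng.uniform(1.5, 6.0)
    kap = kd * rng.uniform(0.1, 0.6)
    s = rng.uniform(0.15, 0.95)
    return PTCRateSet(kpaa=ka, kpda=kd, kpap=s * ka, kpdp=s * kd,
                      ka_prime=kap, kp_prime=s * kap)


@pytest.fixture(scope="module")
def symmetric(fitted_rates):
    """PTC as fast as the adult center (the headline hypothetical)."""
    return ptc_rates_from_adult(fitted_rates, 1.0)


class TestAdultCohort:
    def test_same_as_single_center_chain(self):
        for t in (0.0, 1.0, 4.0):
            assert adult_cohort_at(t, 0.158, 1.151) == simple_model_at(t, RateSet(0.158, 1.151))


class TestRegionOne:
    def test_initial_condition(self, symmetric):
        assert ptc_region1_at(0.0, symmetric) == (1.0, 0.0, 0.0, 0.0)

    def test_no_ptc_reduces_to_simple_model(self, fitted_rates):
        rates = PTCRateSet(kpaa=0.158, kpda=1.151, kpap=0.0, kpdp=1.151,
                           ka_prime=0.122, kp_prime=0.0)
        for t in (0.5, 1.0, 1.4):
            state = ptc_region1_at(t, rates)
            ref = simple_model_at(t, RateSet(0.158, 1.151))
            assert state.Pap == 0.0
            assert state.Ps == pytest.approx(ref.Ns, abs=1e-12)
            assert state.Paa == pytest.approx(ref.Na, abs=1e-12)
            assert state.Pd == pytest.approx(ref.Nd, abs=1e-12)

    def test_symmetric_rates_split_evenly(self, symmetric):
        for t in (0.3, 0.9, 1.4):
            state = ptc_region1_at(t, symmetric)
            assert state.Paa == pytest.approx(state.Pap, rel=1e-12)


class TestBoundaries:
    def test_symmetric_case_saturates_together_then_drains(self, symmetric):
        t1a, t1p, consts = ptc_boundaries(symmetric)
        assert t1p == pytest.approx(t1a, abs=1e-9)
        assert consts.G == pytest.approx(1.0 - consts.C - consts.D, abs=1e-12)
        assert ptc_t2(symmetric) == pytest.approx(4.07, abs=0.01)

    def test_ptc_admission_zero_means_no_ptc_census(self, fitted_rates):
        rates = PTCRateSet(kpaa=0.158, kpda=1.151, kpap=0.0, kpdp=1.151,
                           ka_prime=0.122, kp_prime=0.0)
        _, _, consts = ptc_boundaries(rates)
        assert consts.D == 0.0

    def test_ptc_saturation_is_census_argmax(self, rng):
        for _ in range(5):
            rates = random_ptc_rates(rng)
            t1a, t1p, _ = ptc_boundaries(rates)
            t2 = ptc_t2(rates)
            grid = np.linspace(1e-4, t2 - 1e-4, 40_001)
            pap = np.array([ptc_model_at(float(t), rates)[0].Pap for t in grid])
            dx = grid[1] - grid[0]
            assert t1p == pytest.approx(grid[np.argmax(pap)], abs=2 * dx)

    def test_pediatric_faster_raises_with_relabel_hint(self, fitted_rates):
        rates = PTCRateSet(kpaa=0.158, kpda=1.151, kpap=0.158, kpdp=2.0,
                           ka_prime=0.122, kp_prime=0.122)
        with pytest.raises(PediatricFasterError, match="[Rr]elabel"):
            ptc_boundaries(rates)
        t1a, t1p, _ = ptc_boundaries(rates, allow_relabel=True)
        assert t1p < t1a  # the PTC genuinely saturates first


class TestPiecewiseModel:
    def test_continuity_at_all_breakpoints(self, rng):
        for _ in range(5):
            rates = random_ptc_rates(rng)
            ts = ptc_timescales(rates)
            eps = 1e-10
            for t_star in (ts.t1a, ts.t1p, ts.t2):
                left, _ = ptc_model_at(max(t_star - eps, 0.0), rates)
                right, _ = ptc_model_at(t_star, rates)
                assert np.allclose(left, right, atol=1e-8)

    def test_everyone_discharged_eventually(self, symmetric):
        state, region = ptc_model_at(200.0, symmetric)
        assert region == "IV"
        assert np.allclose(state, (0.0, 0.0, 0.0, 1.0), atol=1e-9)

    def test_census_constant_while_at_capacity(self, rng):
        rates = random_ptc_rates(rng)
        ts = ptc_timescales(rates)
        _, _, consts = ptc_boundaries(rates)
        for t in np.linspace(ts.t1a, ts.t2 - 1e-9, 50):
            assert ptc_model_at(float(t), rates)[0].Paa == pytest.approx(consts.C, abs=1e-12)
        for t in np.linspace(ts.t1p, ts.t2 - 1e-9, 50):
            assert ptc_model_at(float(t), rates)[0].Pap == pytest.approx(consts.D, abs=1e-12)

    def test_conservation_all_regions(self, rng):
        for _ in range(5):
            rates = random_ptc_rates(rng)
            for t in np.linspace(0.0, 25.0, 120):
                state, _ = ptc_model_at(float(t), rates)
                assert sum(state) == pytest.approx(1.0, abs=1e-9)

    def test_matches_numeric_integration(self, rng):
        for _ in range(5):
            rates = random_ptc_rates(rng)
            t2 = ptc_t2(rates)
            t_grid = np.linspace(0.0, t2 + 4.0, 25)
            numeric = integrate(ptc_ode(rates), t_grid, step=1e-3)
            closed = np.array([ptc_model_at(float(t), rates)[0] for t in t_grid])
            np.testing.assert_allclose(closed, numeric, atol=1e-6)

    def test_inactive_ptc_equals_capacity_model(self, fitted_rates):
        rates = PTCRateSet(kpaa=fitted_rates.ka, kpda=fitted_rates.kd, kpap=0.0,
                           kpdp=fitted_rates.kd, ka_prime=fitted_rates.k_prime, kp_prime=0.0)
        for t in np.linspace(0.0, 14.0, 57):
            p, _ = ptc_model_at(float(t), rates)
            c, _ = capacity_model_at(float(t), fitted_rates)
            assert p.Pap == 0.0
            assert np.allclose((p.Ps, p.Paa, p.Pd), tuple(c), atol=1e-12)
        assert ptc_t99(rates) == pytest.approx(capacity_t99(fitted_rates), abs=1e-12)


class TestT99:
    def test_symmetric_rates_halve_the_treatment_time(self, symmetric):
        # t2 from 8 to just over 4 days; t99 from 10 to a little over 6.5
        assert 4.0 < ptc_t2(symmetric) < 4.5
        assert 6.5 < ptc_t99(symmetric) < 7.0

    def test_threshold_at_queue_exhaustion_returns_t2(self, symmetric):
        _, _, consts = ptc_boundaries(symmetric)
        assert ptc_t99(symmetric, threshold=consts.G) == pytest.approx(ptc_t2(symmetric))

    def test_root_self_consistency(self, rng):
        for _ in range(5):
            rates = random_ptc_rates(rng)
            t99 = ptc_t99(rates)
            assert ptc_model_at(t99, rates)[0].Pd == pytest.approx(0.99, abs=1e-9)

    def test_t2_is_region_three_root(self, rng):
        # t2 is the t-intercept of the linear region-III queue decline
        rates = random_ptc_rates(rng)
        ts = ptc_timescales(rates)
        ta = ts.t1p + 0.1 * (ts.t2 - ts.t1p)
        tb = ts.t1p + 0.6 * (ts.t2 - ts.t1p)
        ps_a = ptc_model_at(ta, rates)[0].Ps
        ps_b = ptc_model_at(tb, rates)[0].Ps
        root = brentq(lambda t: ps_a + (ps_b - ps_a) * (t - ta) / (tb - ta),
                      ts.t1p, ts.t2 + 1.0, xtol=1e-12)
        assert root == pytest.approx(ts.t2, abs=1e-9)

    def test_timescales_ordered(self, rng):
        for _ in range(5):
            ts = ptc_timescales(random_ptc_rates(rng))
            assert 0 < ts.t1a <= ts.t1p <= ts.t2 < ts.t99
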