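"""Analytic and numeric sensitivity/variance matrices."""

from dataclasses import replace

import numpy as np
import pytest

from surgekinetics import (
    RateSet,
    analytic_sensitivity_capacity,
    capacity_breakpoints,
    capacity_t99,
    numeric_sensitivity_ptc,
    ptc_rates_from_adult,
    ptc_sensitivity_sigmas,
    variance_matrix,
)

from conftest import random_capacity_rates


def finite_difference_S(rates: RateSet, rel_step: float = 1e-6) -> np.ndarray:
    """Central differences of (t1, t2, t99) w.r.t. (ka, kd, k')."""
    def outputs(r: RateSet) -> np.ndarray:
        ts = capacity_breakpoints(r)
        return np.array([ts.t1, ts.t2, capacity_t99(r)])

    S = np.empty((3, 3))
    for j, name in enumerate(("ka", "kd", "k_prime")):
        p = getattr(rates, name)
        h = rel_step * p
        S[:, j] = (outputs(replace(rates, **{name: p + h}))
                   - outputs(replace(rates, **{name: p - h}))) / (2 * h)
    return S


class TestAnalyticCapacity:
    def test_fitted_scenario_matrix(self, fitted_rates):
        S = analytic_sensitivity_capacity(fitted_rates)
        expected = np.array([
            [-4.36, -1.14, 0.0],
            [-12.23, -0.06, -49.37],
            [-7.87, -2.40, -49.37],
        ])
        np.testing.assert_allclose(S, expected, rtol=0.02, atol=0.005)

    def test_t1_independent_of_throughput(self, rng):
        for _ in range(5):
            S = analytic_sensitivity_capacity(random_capacity_rates(rng))
            assert S[0, 2] == 0.0

    def test_t2_throughput_sensitivity_always_negative(self, rng):
        for _ in range(5):
            rates = random_capacity_rates(rng)
            S = analytic_sensitivity_capacity(rates)
            assert S[1, 2] == pytest.approx(
                -np.exp(-rates.ka * capacity_breakpoints(rates).t1) / rates.k_prime ** 2)
            assert S[1, 2] < 0

    def test_matches_finite_differences(self, rng):
        for _ in range(20):
            rates = random_capacity_rates(rng)
            S = analytic_sensitivity_capacity(rates)
            S_fd = finite_difference_S(rates)
            np.testing.assert_allclose(S, S_fd, rtol=1e-4, atol=1e-8)

    def test_degenerate_rates_rejected(self):
        with pytest.raises(ValueError, match="ka == kd"):
            analytic_sensitivity_capacity(RateSet(1.0, 1.0, 0.5))


class TestVarianceMatrix:
    def test_fitted_scenario_values(self, haiti_fit):
        S = analytic_sensitivity_capacity(haiti_fit.rates)
        V = variance_matrix(S, haiti_fit.sigmas)
        assert V[0, 0] == pytest.approx(0.082, rel=0.05)
        assert V[2, 1] == pytest.approx(0.815, rel=0.05)

    def test_zero_sigmas_give_zero_matrix(self, fitted_rates):
        S = analytic_sensitivity_capacity(fitted_rates)
        assert np.all(variance_matrix(S, np.zeros(3)) == 0.0)

    def test_definition_and_nonnegativity(self, haiti_fit):
        S = analytic_sensitivity_capacity(haiti_fit.rates)
        V = variance_matrix(S, haiti_fit.sigmas)
        np.testing.assert_array_equal(V, S ** 2 * haiti_fit.sigmas ** 2)
        assert np.all(V >= 0)

    def test_from_finite_difference_S_agrees(self, haiti_fit):
        V = variance_matrix(analytic_sensitivity_capacity(haiti_fit.rates), haiti_fit.sigmas)
        V_fd = variance_matrix(finite_difference_S(haiti_fit.rates), haiti_fit.sigmas)
        np.testing.assert_allclose(V, V_fd, rtol=0.01, atol=1e-12)

    def test_discharge_rate_dominates_treatment_time(self, haiti_fit):
        # the t99 row of V is largest in the kd column: rapid pre-capacity
        # discharge matters most for total treatment time
        V = variance_matrix(analytic_sensitivity_capacity(haiti_fit.rates), haiti_fit.sigmas)
        assert np.argmax(V[2]) == 1

    def test_sigma_shape_validated(self, fitted_rates):
        S = analytic_sensitivity_capacity(fitted_rates)
        with pytest.raises(ValueError, match="sigmas"):
            variance_matrix(S, np.ones(2))


@pytest.fixture(scope="module")
def result(haiti_fit):
    ptc = ptc_rates_from_adult(haiti_fit.rates, 1.0)
    return numeric_sensitivity_ptc(ptc, ptc_sensitivity_sigmas(ptc, haiti_fit.sigmas))


class TestNumericPTC:
    def test_shape_and_labels(self, result):
        assert result.S.shape == result.V.shape == (4, 6)
        assert result.output_labels == ("t1a", "t1p", "t2", "t99")
        assert result.parameter_labels[1] == "kpap"

    def test_steady_state_ptc_rate_dominates(self, result):
        # kp' carries the largest variance contribution to both t2 and t99
        assert result.parameter_labels[np.argmax(result.V[2])] == "kp_prime"
        assert result.parameter_labels[np.argmax(result.V[3])] == "kp_prime"
        assert result.V[2, 5] == pytest.approx(4.645, rel=0.05)
        assert result.V[3, 5] == pytest.approx(4.690, rel=0.05)

    def test_saturation_times_ignore_steady_state_rates(self, result):
        # region I/II kinetics never see ka' beyond the adult queue drain,
        # and neither saturation time depends on kp'
        np.testing.assert_allclose(result.S[0, 4:], 0.0, atol=1e-9)
        assert result.S[1, 5] == pytest.approx(0.0, abs=1e-9)

    def test_t99_throughput_sensitivity_equals_t2(self, result):
        # after the queue vanishes the relaxation is independent of kp',
        # so dt99/dkp' = dt2/dkp' exactly
        assert result.S[3, 5] == pytest.approx(result.S[2, 5], abs=1e-6)

    def test_step_halving_stability(self, haiti_fit):
        ptc = ptc_rates_from_adult(haiti_fit.rates, 1.0)
        sig = ptc_sensitivity_sigmas(ptc, haiti_fit.sigmas)
        S1 = numeric_sensitivity_ptc(ptc, sig, step=0.001).S
        S2 = numeric_sensitivity_ptc(ptc, sig, step=0.0005).S
        mask = np.abs(S1) > 1e-6
        np.testing.assert_allclose(S1[mask], S2[mask], rtol=0.01)

    def test_zero_sigmas_zero_variance(self, haiti_fit):
        ptc = ptc_rates_from_adult(haiti_fit.rates, 1.0)
        res = numeric_sensitivity_ptc(ptc, np.zeros(6))
        assert np.all(res.V == 0.0)

    def test_sigma_convention(self, haiti_fit):
        ptc = ptc_rates_from_adult(haiti_fit.rates, 1.0)
        sig = ptc_sensitivity_sigmas(ptc, haiti_fit.sigmas)
        # adult-center-side rates reuse the fitted uncertainties
        assert sig[0] == haiti_fit.sigmas[0]
        assert sig[2] == haiti_fit.sigmas[1]
        assert sig[4] == haiti_fit.sigmas[2]
        # PTC-side variances are 35% of the parameter value
        assert sig[3] ** 2 == pytest.approx(0.35 * ptc.kpdp)
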