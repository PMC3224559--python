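"""Local sensitivity and variance analysis of the timescale outputs.

For a model output ``X_i`` and parameters ``p_j`` with uncertainties
``sigma_j`` (covariances neglected), the sensitivity matrix and the
variance-contribution matrix are

    S_ij = dX_i / dp_j          V_ij = S_ij^2 * sigma_j^2,

so that ``sum_j V_ij`` is the output variance and the ranking of a row of
``V`` ranks the parameters' influence on that output.

For the single-center capacity model the nine partials of (t1, t2, t99)
with respect to (ka, kd, k') are available in closed form and implemented
here.  For the two-center PTC model the four outputs (t1a, t1p, t2, t99)
are differentiated numerically: each of the six rates is incremented by
an absolute +/- step (default 0.001 day^-1) and the forward and backward
one-sided differences are averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import RateSet
from .ptc import PTCRateSet, ptc_timescales

__all__ = [
    "SensitivityResult",
    "CAPACITY_OUTPUTS",
    "CAPACITY_PARAMETERS",
    "PTC_OUTPUTS",
    "PTC_PARAMETERS",
    "analytic_sensitivity_capacity",
    "variance_matrix",
    "capacity_sensitivity",
    "numeric_sensitivity_ptc",
    "ptc_sensitivity_sigmas",
]

CAPACITY_OUTPUTS = ("t1", "t2", "t99")
CAPACITY_PARAMETERS = ("ka", "kd", "k_prime")
PTC_OUTPUTS = ("t1a", "t1p", "t2", "t99")
PTC_PARAMETERS = ("kpaa", "kpap", "kpda", "kpdp", "ka_prime", "kp_prime")


@dataclass(frozen=True)
class SensitivityResult:
    """Sensitivity matrix ``S``, variance matrix ``V = S^2 sigma^2``
    (elementwise, sigma broadcast over columns), and the labels."""

    S: np.ndarray
    V: np.ndarray
    output_labels: tuple[str, ...]
    parameter_labels: tuple[str, ...]
    sigmas: np.ndarray


def analytic_sensitivity_capacity(rates: RateSet, threshold: float = 0.99) -> np.ndarray:
    """Closed-form 3x3 sensitivity matrix of the capacity model.

    Rows (t1, t2, t99) x columns (ka, kd, k').  Derivatives of t99 use the
    region-III closed form ``t99 = t2 - ln((1-threshold)/Na^max)/kd``
    (``Nd + Na = 1`` once the queue is gone).  ``t1`` does not depend on
    ``k'``, and ``Nd(t2)`` does not depend on ``k'`` either (region II
    converts the remaining queue into discharges one-for-one), so
    ``dt99/dk' = dt2/dk'``.
    """
    ka, kd, kp = rates.ka, rates.kd, rates.k_prime
    if rates.is_degenerate:
        raise ValueError("analytic sensitivities are singular at ka == kd")
    d = kd - ka
    t1 = math.log(kd / ka) / d
    e1 = math.exp(-ka * t1)
    ed1 = math.exp(-kd * t1)
    na1 = ka / d * (e1 - ed1)

    dt1_dka = (t1 - 1.0 / ka) / d
    dt1_dkd = (1.0 / kd - t1) / d

    common = 1.0 - ka / kp * e1
    dt2_dka = common * dt1_dka - t1 / kp * e1
    dt2_dkd = common * dt1_dkd
    dt2_dkp = -e1 / (kp * kp)

    # Na^max: the time-derivative term vanishes at the maximum (envelope),
    # but the explicit t1 dependence is kept for transparency with the
    # chain-rule forms; both agree.
    dna1_dka = kd / d ** 2 * (e1 - ed1) - t1 * ka / d * e1
    dna1_dkd = -ka / d ** 2 * (e1 - ed1) + t1 * ka / d * ed1

    log_term = math.log((1.0 - threshold) / na1)
    dt99_dka = dt2_dka + dna1_dka / (na1 * kd)
    dt99_dkd = dt2_dkd + dna1_dkd / (na1 * kd) + log_term / kd ** 2
    dt99_dkp = dt2_dkp

    return np.array([
        [dt1_dka, dt1_dkd, 0.0],
        [dt2_dka, dt2_dkd, dt2_dkp],
        [dt99_dka, dt99_dkd, dt99_dkp],
    ])


def variance_matrix(S: np.ndarray, sigmas) -> np.ndarray:
    """Elementwise ``V_ij = S_ij^2 sigma_j^2`` (sigmas indexed by column)."""
    sigmas = np.asarray(sigmas, dtype=float)
    if sigmas.shape != (S.shape[1],):
        raise ValueError(f"expected {S.shape[1]} sigmas (one per parameter column), got {sigmas.shape}")
    return S ** 2 * sigmas ** 2


def capacity_sensitivity(rates: RateSet, sigmas, threshold: float = 0.99) -> SensitivityResult:
    """Analytic S and V for the capacity model, packaged with labels."""
    S = analytic_sensitivity_capacity(rates, threshold)
    sigmas = np.asarray(sigmas, dtype=float)
    return SensitivityResult(S=S, V=variance_matrix(S, sigmas),
                             output_labels=CAPACITY_OUTPUTS,
                             parameter_labels=CAPACITY_PARAMETERS, sigmas=sigmas)


def _ptc_outputs(rates: PTCRateSet, threshold: float) -> np.ndarray:
    # Continuation mode: at the symmetric baseline the physical timescales
    # have an exchange-symmetry kink where the saturation order flips;
    # difference quotients use the smooth adult-faster branch instead.
    ts = ptc_timescales(rates, threshold=threshold, continuation=True)
    return np.array([ts.t1a, ts.t1p, ts.t2, ts.t99])


def numeric_sensitivity_ptc(rates: PTCRateSet, sigmas, step: float = 0.001,
                            threshold: float = 0.99) -> SensitivityResult:
    """Numeric 4x6 sensitivity of the PTC model's timescales.

    Each parameter is perturbed by an absolute ``+/- step`` (day^-1) and
    the forward/backward one-sided differences are averaged (equivalently,
    the central difference).  Perturbations that make the PTC marginally
    the faster center are evaluated on the smooth continuation of the
    adult-faster closed forms (the physical solution has an
    exchange-symmetry kink there).  Evaluation failures are re-raised
    naming the offending parameter.
    """
    sigmas = np.asarray(sigmas, dtype=float)
    S = np.empty((4, 6))
    for j, name in enumerate(PTC_PARAMETERS):
        p = getattr(rates, name)
        try:
            up = _ptc_outputs(replace(rates, **{name: p + step}), threshold)
            dn = _ptc_outputs(replace(rates, **{name: p - step}), threshold)
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(
                f"sensitivity evaluation failed while incrementing {name} by +/-{step}: {exc}"
            ) from exc
        S[:, j] = (up - dn) / (2.0 * step)
    return SensitivityResult(S=S, V=variance_matrix(S, sigmas),
                             output_labels=PTC_OUTPUTS,
                             parameter_labels=PTC_PARAMETERS, sigmas=sigmas)


def ptc_sensitivity_sigmas(rates: PTCRateSet, fit_sigmas,
                           pediatric_variance_fraction: float = 0.35) -> np.ndarray:
    """Parameter uncertainties for the PTC sensitivity analysis.

    The adult-center-side rates (kpaa, kpda, ka') carry the uncertainties
    fitted from the historical data (``fit_sigmas`` in ka, kd, k' order);
    no data exist for the PTC-side rates (kpap, kpdp, kp'), whose variance
    is set to a fraction (default 35%%) of the parameter value itself.
    Order matches :data:`PTC_PARAMETERS`.
    """
    s_ka, s_kd, s_kp = (float(s) for s in fit_sigmas)
    return np.array([
        s_ka,
        math.sqrt(pediatric_variance_fraction * rates.kpap),
        s_kd,
        math.sqrt(pediatric_variance_fraction * rates.kpdp),
        s_kp,
        math.sqrt(pediatric_variance_fraction * rates.kp_prime),
    ])
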