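"""Two-center maximum-capacity model with a pediatric trauma center (PTC).

The pediatric cohort ``P0`` can be triaged either to the adult center
(admission ``kpaa``, discharge ``kpda``) or to the PTC (``kpap``,
``kpdp``); adults are never triaged to the PTC.  With the adult center
saturating first, the pediatric cohort passes through four regimes:

    region I   — neither center full: linear kinetics, total admission
                 rate k = kpaa + kpap
    region II  — adult center at capacity (zeroth-order throughput ka'),
                 PTC still admitting first-order
    region III — both centers at capacity, combined zeroth-order
                 throughput kappa = ka' + kp'
    region IV  — surge exhausted, both centers discharge exponentially

The derivation requires the adult center to saturate first, which holds
exactly when ``kpdp <= kpda``.  When the PTC is the faster center the
model is recovered by swapping the two centers' rate labels; the solver
either raises or performs that swap (``allow_relabel=True``), reporting
compartments and saturation times under their physical labels.

All populations are fractions of the pediatric cohort (P0 = 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple

from scipy.optimize import brentq

from .core import DEGENERACY_RTOL, DegenerateRatesError, RateSet, simple_model_at
from .capacity import capacity_t99

__all__ = [
    "PTCRateSet",
    "CohortSplit",
    "PTCBoundaryConstants",
    "PTCTimescales",
    "PTCPopulationState",
    "PediatricFasterError",
    "adult_cohort_at",
    "ptc_region1_at",
    "ptc_boundaries",
    "ptc_model_at",
    "ptc_t2",
    "ptc_t99",
    "ptc_timescales",
]


class PediatricFasterError(ValueError):
    """The PTC would saturate before the adult center (``kpdp > kpda``).

    The derivation assumes the adult center is the faster one; the same
    model applies to the opposite case after relabeling the two centers'
    rate constants (swap kpaa<->kpap, kpda<->kpdp, ka'<->kp'), or pass
    ``allow_relabel=True`` to have the solver do this transparently.
    """


@dataclass(frozen=True)
class PTCRateSet:
    """Rate constants of the two-center model (all day^-1 except the
    zeroth-order throughputs, fraction of P0 per day).

    ``kaa``/``kad`` are the adult cohort's own admission/discharge rates;
    they default to the pediatric-at-adult-center values and only matter
    for :func:`adult_cohort_at`.
    """

    kpaa: float
    kpda: float
    kpap: float
    kpdp: float
    ka_prime: float
    kp_prime: float
    kaa: float = math.nan
    kad: float = math.nan

    def __post_init__(self) -> None:
        for name in ("kpaa", "kpda", "ka_prime"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.kpap < 0 or self.kp_prime < 0:
            raise ValueError("PTC rates must be nonnegative")
        if self.kpap == 0 and self.kp_prime > 0:
            raise ValueError("kp_prime > 0 is meaningless when the PTC admits no patients (kpap = 0)")
        if self.kpap > 0 and not self.kpdp > 0:
            raise ValueError("kpdp must be positive when the PTC admits patients")
        if math.isnan(self.kaa):
            object.__setattr__(self, "kaa", self.kpaa)
        if math.isnan(self.kad):
            object.__setattr__(self, "kad", self.kpda)

    @property
    def k(self) -> float:
        """Total pediatric admission rate ``kpaa + kpap``."""
        return self.kpaa + self.kpap

    @property
    def kappa(self) -> float:
        """Combined at-capacity throughput ``ka' + kp'``."""
        return self.ka_prime + self.kp_prime

    @property
    def ptc_inactive(self) -> bool:
        """True when the PTC admits no patients; the pediatric cohort then
        sees a single center and the model collapses to the single-center
        capacity model."""
        return self.kpap == 0.0

    def relabeled(self) -> "PTCRateSet":
        """Swap the two centers' rate constants."""
        return replace(
            self,
            kpaa=self.kpap, kpap=self.kpaa,
            kpda=self.kpdp, kpdp=self.kpda,
            ka_prime=self.kp_prime, kp_prime=self.ka_prime,
        )


@dataclass(frozen=True)
class CohortSplit:
    """Initial adult/pediatric split of the surge, ``A0 + P0 = N0``."""

    A0: float
    P0: float

    def __post_init__(self) -> None:
        if self.A0 < 0 or self.P0 < 0:
            raise ValueError("cohort sizes must be nonnegative")

    @property
    def N0(self) -> float:
        return self.A0 + self.P0


class PTCPopulationState(NamedTuple):
    """Pediatric-cohort fractions: surge, at adult center, at PTC, discharged."""

    Ps: float
    Paa: float
    Pap: float
    Pd: float


@dataclass(frozen=True)
class PTCBoundaryConstants:
    """Region-boundary constants of the piecewise solution.

    ``A, C, H, E`` are the region-I exit values of (Ps, Paa, Pap, Pd) at
    t1a; ``alpha, gamma, beta`` the region-II integration constants;
    ``B, D, F`` the region-II exit values of (Ps, Pap, Pd) at t1p; and
    ``G = F + B`` the discharged fraction when the queue vanishes at t2.
    ``D`` is the PTC census held through region III — identically zero iff
    the PTC admits no patients.
    """

    A: float
    C: float
    H: float
    E: float
    alpha: float
    gamma: float
    beta: float
    B: float
    D: float
    F: float
    G: float


@dataclass(frozen=True)
class PTCTimescales:
    """Center saturation times, queue-exhaustion time and discharge time
    (days), under physical labels (``t1a`` = adult center, ``t1p`` = PTC).
    When ``relabeled`` is True the PTC was the faster center and
    ``t1p < t1a``."""

    t1a: float
    t1p: float
    t2: float
    t99: float = math.nan
    relabeled: bool = False


@dataclass(frozen=True)
class _Solution:
    """Solver-oriented solution (the 'a' labels are the faster center)."""

    rates: PTCRateSet
    t1a: float
    t1p: float
    t2: float
    consts: PTCBoundaryConstants
    relabeled: bool


def adult_cohort_at(t: float, kaa: float, kad: float):
    """Unconstrained adult-cohort populations ``(As, Aa, Ad)`` — the
    three-compartment chain with relabeled rates."""
    return simple_model_at(t, RateSet(ka=kaa, kd=kad))


def _as_capacity_rateset(rates: PTCRateSet) -> RateSet:
    # PTC inactive: pediatric cohort flows through the adult center only.
    return RateSet(ka=rates.kpaa, kd=rates.kpda, k_prime=rates.ka_prime)


def ptc_region1_at(t: float, rates: PTCRateSet) -> PTCPopulationState:
    """Region-I (neither center full) closed forms, valid on [0, t1a).

    Near-degenerate denominators (``kpda ~= k`` or ``kpdp ~= k``) switch to
    the removable-singularity limit forms ``kp.. * t * exp(-k t)``.
    """
    if t < 0:
        raise ValueError(f"time must be nonnegative, got t={t}")
    k = rates.k
    es = math.exp(-k * t)
    paa = _rise_decay(rates.kpaa, k, rates.kpda, t, es)
    pap = _rise_decay(rates.kpap, k, rates.kpdp, t, es) if rates.kpap > 0 else 0.0
    return PTCPopulationState(es, paa, pap, 1.0 - es - paa - pap)


def _rise_decay(k_in: float, k_fast: float, k_out: float, t: float, e_fast: float) -> float:
    """k_in/(k_out - k_fast) (e^-k_fast t - e^-k_out t), with its equal-rate limit."""
    if abs(k_out - k_fast) <= DEGENERACY_RTOL * max(k_out, k_fast):
        return k_in * t * e_fast
    return k_in / (k_out - k_fast) * (e_fast - math.exp(-k_out * t))


def _solve_oriented(rates: PTCRateSet, continuation: bool = False) -> _Solution:
    """Boundary constants assuming the 'a'-labeled center saturates first.

    With ``continuation=True`` the adult-faster closed forms are extended
    smoothly across the validity boundary (``t1p`` may fall before
    ``t1a``, leaving region II empty); used for one-sided derivatives at
    the symmetric-rates kink, where the physical solution switches branch
    by relabeling.
    """
    k = rates.k
    kpda, kpdp, kpap, kap, kpp = rates.kpda, rates.kpdp, rates.kpap, rates.ka_prime, rates.kp_prime

    # t1a: argmax of the region-I adult-center census.
    if abs(kpda - k) <= DEGENERACY_RTOL * max(kpda, k):
        t1a = 1.0 / k
    else:
        t1a = math.log(kpda / k) / (kpda - k)
    A, C, H, E = ptc_region1_at(t1a, rates)
    Hap = H  # region-I exit value of the PTC census
    E = 1.0 - A - C - Hap

    if rates.ptc_inactive:
        # Single active center: region II is the linear at-capacity regime,
        # exhausted at t2 = t1a + A/ka'; there is no PTC saturation.
        t2 = t1a + A / kap
        consts = PTCBoundaryConstants(
            A=A, C=C, H=0.0, E=E,
            alpha=math.nan, gamma=math.nan, beta=math.nan,
            B=0.0, D=0.0, F=E + A, G=E + A,
        )
        return _Solution(rates, t1a, t2, t2, consts, relabeled=False)

    if abs(kpdp - kpap) <= DEGENERACY_RTOL * max(kpdp, kpap):
        raise DegenerateRatesError(
            f"region-II closed form is singular at kpdp == kpap (both {kpdp}); no limit form implemented"
        )
    alpha = A + kap / kpap
    gamma = (A * kpap + kap) / (kpdp - kpap)
    beta = Hap - gamma + kap / kpdp

    # t1p: argmax of the region-II PTC census Pap(dt) = -ka'/kpdp
    #      + gamma e^{-kpap dt} + beta e^{-kpdp dt}.
    arg = -(kpdp * beta) / (kpap * gamma)
    if arg <= 0.0:
        raise ValueError(
            "PTC saturation time is undefined for these rates: the log argument "
            f"-kpdp*beta/(kpap*gamma) = {arg:.3e} is nonpositive (beta={beta:.3e}, gamma={gamma:.3e})"
        )
    dt1 = math.log(arg) / (kpdp - kpap)
    if dt1 < 0.0 and not continuation:
        # kpdp <= kpda guarantees the PTC census is still rising at t1a, so a
        # negative offset can only be rounding noise from the symmetric case.
        if dt1 < -1e-6 * max(t1a, 1.0):
            raise RuntimeError(
                f"inconsistent region-II maximum (offset {dt1:.3e} d before t1a); "
                "check the adult-faster orientation of the rates"
            )
        dt1 = 0.0
    t1p = t1a + dt1

    e_ap = math.exp(-kpap * dt1)
    e_dp = math.exp(-kpdp * dt1)
    B = -kap / kpap + alpha * e_ap
    D = -kap / kpdp + gamma * e_ap + beta * e_dp
    F = beta * (1.0 - e_dp) + gamma * kpdp / kpap * (1.0 - e_ap) + E
    G = F + B
    t2 = t1p + B / rates.kappa
    consts = PTCBoundaryConstants(A=A, C=C, H=Hap, E=E, alpha=alpha, gamma=gamma,
                                  beta=beta, B=B, D=D, F=F, G=G)
    return _Solution(rates, t1a, t1p, t2, consts, relabeled=False)


def _solve(rates: PTCRateSet, allow_relabel: bool = False, continuation: bool = False) -> _Solution:
    if rates.ptc_inactive or rates.kpdp <= rates.kpda * (1.0 + DEGENERACY_RTOL):
        return _solve_oriented(rates, continuation)
    if continuation:
        return _solve_oriented(rates, continuation=True)
    if not allow_relabel:
        raise PediatricFasterError(
            f"kpdp={rates.kpdp} > kpda={rates.kpda}: the PTC saturates before the adult center. "
            "Relabel the centers' rate constants (swap kpaa<->kpap, kpda<->kpdp, ka'<->kp') "
            "or pass allow_relabel=True."
        )
    sol = _solve_oriented(rates.relabeled())
    return replace(sol, relabeled=True)


def ptc_boundaries(rates: PTCRateSet, allow_relabel: bool = False) -> tuple[float, float, PTCBoundaryConstants]:
    """Saturation times ``(t1a, t1p)`` (physical labels) and the boundary
    constants.  Raises :class:`PediatricFasterError` when the PTC would
    saturate first, unless ``allow_relabel`` is set."""
    sol = _solve(rates, allow_relabel)
    if sol.relabeled:
        return sol.t1p, sol.t1a, sol.consts
    return sol.t1a, sol.t1p, sol.consts


def ptc_t2(rates: PTCRateSet, allow_relabel: bool = False) -> float:
    """Queue-exhaustion time ``t2 = t1p + B/kappa`` (days)."""
    return _solve(rates, allow_relabel).t2


def _model_at_oriented(t: float, sol: _Solution) -> tuple[PTCPopulationState, str]:
    rates = sol.rates
    c = sol.consts
    if t < sol.t1a:
        return ptc_region1_at(t, rates), "I"
    if rates.ptc_inactive:
        if t < sol.t2:
            dt = t - sol.t1a
            ps = max(c.A - rates.ka_prime * dt, 0.0)
            return PTCPopulationState(ps, c.C, 0.0, c.E + rates.ka_prime * dt), "II"
        paa = c.C * math.exp(-rates.kpda * (t - sol.t2))
        return PTCPopulationState(0.0, paa, 0.0, 1.0 - paa), "IV"
    if t < sol.t1p:
        dt = t - sol.t1a
        e_ap = math.exp(-rates.kpap * dt)
        e_dp = math.exp(-rates.kpdp * dt)
        ps = -rates.ka_prime / rates.kpap + c.alpha * e_ap
        pap = -rates.ka_prime / rates.kpdp + c.gamma * e_ap + c.beta * e_dp
        pd = c.beta * (1.0 - e_dp) + c.gamma * rates.kpdp / rates.kpap * (1.0 - e_ap) + c.E
        return PTCPopulationState(ps, c.C, pap, pd), "II"
    if t < sol.t2:
        dt = t - sol.t1p
        ps = max(c.B - rates.kappa * dt, 0.0)
        return PTCPopulationState(ps, c.C, c.D, c.F + rates.kappa * dt), "III"
    dt = t - sol.t2
    paa = c.C * math.exp(-rates.kpda * dt)
    pap = c.D * math.exp(-rates.kpdp * dt)
    return PTCPopulationState(0.0, paa, pap, 1.0 - paa - pap), "IV"


def ptc_model_at(t: float, rates: PTCRateSet, allow_relabel: bool = False) -> tuple[PTCPopulationState, str]:
    """Evaluate the piecewise two-center model at time ``t`` (days).

    Returns the pediatric-cohort fractions (physical compartment labels)
    and the region label I-IV.
    """
    if t < 0:
        raise ValueError(f"time must be nonnegative, got t={t}")
    sol = _solve(rates, allow_relabel)
    state, region = _model_at_oriented(t, sol)
    if sol.relabeled:
        state = PTCPopulationState(state.Ps, state.Pap, state.Paa, state.Pd)
    return state, region


def ptc_t99(rates: PTCRateSet, threshold: float = 0.99, allow_relabel: bool = False) -> float:
    """Time (days) at which the discharged pediatric fraction reaches
    ``threshold`` (default 99%).

    Region IV's discharged fraction ``Pd = 1 - C e^{-kpda dt} - D e^{-kpdp dt}``
    is transcendental, so the time is found by bracketed root finding on
    ``[t2, t2 + 1e3/min(kpda, kpdp)]`` (monotone, so the bracket is
    guaranteed once Pd(t2) < threshold).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return _t99_from(_solve(rates, allow_relabel), threshold)


def _t99_from(sol: _Solution, threshold: float) -> float:
    rates_o = sol.rates
    if rates_o.ptc_inactive:
        cap = _as_capacity_rateset(rates_o)
        return capacity_t99(cap, threshold)
    g = sol.consts.G
    if threshold == g:
        return sol.t2
    if threshold < g:
        warnings.warn(
            f"threshold {threshold} is reached before the queue is exhausted (Pd(t2) = {g:.4f}); "
            "solving in regions I-III",
            stacklevel=2,
        )
        return brentq(lambda t: _model_at_oriented(t, sol)[0].Pd - threshold, 0.0, sol.t2, xtol=1e-12)
    horizon = sol.t2 + 1e3 / min(rates_o.kpda, rates_o.kpdp)
    pd_end = _model_at_oriented(horizon, sol)[0].Pd
    if pd_end < threshold:
        raise RuntimeError(
            f"failed to bracket t99: Pd({horizon:.1f} d) = {pd_end:.6f} < threshold {threshold} "
            f"(Pd(t2) = {g:.6f})"
        )
    return brentq(lambda t: _model_at_oriented(t, sol)[0].Pd - threshold, sol.t2, horizon, xtol=1e-12)


def ptc_timescales(rates: PTCRateSet, threshold: float = 0.99, allow_relabel: bool = False,
                   continuation: bool = False) -> PTCTimescales:
    """All four timescales of the model under physical labels.

    ``continuation=True`` evaluates the adult-faster closed forms extended
    smoothly across the validity boundary instead of relabeling (used for
    numeric differentiation at the symmetric-rates kink).
    """
    sol = _solve(rates, allow_relabel, continuation)
    t99 = _t99_from(sol, threshold)
    t1a, t1p = (sol.t1p, sol.t1a) if sol.relabeled else (sol.t1a, sol.t1p)
    return PTCTimescales(t1a=t1a, t1p=t1p, t2=sol.t2, t99=t99, relabeled=sol.relabeled)
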