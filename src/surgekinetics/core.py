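"""Closed-form kinetics of the unconstrained surge model.

The surge cohort after a sudden mass-casualty event is treated as a fluid
(deterministic) queue flowing through sequential compartments,

    Ns --ka--> Na --kd--> Nd,

where ``Ns`` is the population awaiting admission, ``Na`` the admitted
census and ``Nd`` the discharged population.  All populations are tracked
as fractions of the initial cohort size N0 = 1; rates are first-order and
carry units of day^-1.  The same chain with an upstream exposure
compartment (``Ne --ks--> Ns --...``) models a surge that develops with a
delay after the inciting event.

Everything here is a closed-form solution of the linear ODE system (the
classic sequential-decay / Bateman chain); the piecewise capacity-limited
variants build on these forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "DEGENERACY_RTOL",
    "DegenerateRatesError",
    "RateSet",
    "DelayedRateSet",
    "PopulationState",
    "DelayedPopulationState",
    "simple_model_at",
    "time_of_max_admitted",
    "max_admitted_fraction",
    "delayed_model_at",
    "time_of_max_surge_delayed",
]

#: Relative tolerance below which two rate constants are treated as equal
#: and the analytic (L'Hopital) limit forms are used instead of the generic
#: closed forms, which have removable singularities at equal rates.
DEGENERACY_RTOL = 1e-8


class DegenerateRatesError(ValueError):
    """Raised when equal rate constants make a closed form singular and no
    limit form is implemented for the requested quantity."""


def _is_close(a: float, b: float, rtol: float = DEGENERACY_RTOL) -> bool:
    return abs(a - b) <= rtol * max(abs(a), abs(b))


@dataclass(frozen=True)
class RateSet:
    """Rate constants of the single-center model.

    Parameters
    ----------
    ka : float
        Pre-capacity admission rate constant (day^-1).
    kd : float
        Pre-capacity discharge rate constant (day^-1).
    k_prime : float
        Zeroth-order throughput rate while the center is at capacity
        (fraction of N0 per day).  One admission per discharge, and assumed
        no faster than the pre-capacity discharge rate (``k_prime <= kd``).
    """

    ka: float
    kd: float
    k_prime: float = math.nan

    def __post_init__(self) -> None:
        if not self.ka > 0 or not self.kd > 0:
            raise ValueError(f"rate constants must be positive, got ka={self.ka}, kd={self.kd}")
        if not math.isnan(self.k_prime):
            if not self.k_prime > 0:
                raise ValueError(f"k_prime must be positive, got {self.k_prime}")
            if self.k_prime > self.kd * (1.0 + DEGENERACY_RTOL):
                raise ValueError(
                    "the at-capacity throughput rate k_prime is assumed no faster "
                    f"than the pre-capacity discharge rate kd (k_prime={self.k_prime} > kd={self.kd})"
                )

    @property
    def is_degenerate(self) -> bool:
        """True when ``ka`` and ``kd`` are equal within :data:`DEGENERACY_RTOL`."""
        return _is_close(self.ka, self.kd)


@dataclass(frozen=True)
class DelayedRateSet:
    """Rates of the delayed-surge chain ``Ne -ks-> Ns -ka-> Na -kd-> Nd``.

    ``ks`` (day^-1) is the exposure/delay rate at which the affected
    population develops into the treatment-seeking surge.  The closed forms
    require the three rates to be pairwise distinct.
    """

    ks: float
    ka: float
    kd: float

    def __post_init__(self) -> None:
        if not (self.ks > 0 and self.ka > 0 and self.kd > 0):
            raise ValueError("all rate constants must be positive")

    def require_distinct(self) -> None:
        pairs = (("ks", self.ks, "ka", self.ka),
                 ("ks", self.ks, "kd", self.kd),
                 ("ka", self.ka, "kd", self.kd))
        for n1, v1, n2, v2 in pairs:
            if _is_close(v1, v2):
                raise DegenerateRatesError(
                    f"delayed-model closed form requires pairwise-distinct rates; {n1}={v1} ~= {n2}={v2}"
                )


class PopulationState(NamedTuple):
    """Population fractions of the three-compartment chain (sum to 1)."""

    Ns: float
    Na: float
    Nd: float


class DelayedPopulationState(NamedTuple):
    """Population fractions of the four-compartment delayed chain."""

    Ne: float
    Ns: float
    Na: float
    Nd: float


def simple_model_at(t: float, rates: RateSet) -> PopulationState:
    """Evaluate the unconstrained model at time ``t`` (days).

    Returns the closed-form fractions

        Ns = exp(-ka t)
        Na = ka/(kd-ka) (exp(-ka t) - exp(-kd t))
        Nd = 1 - Ns - Na  (its own closed form; conservation holds exactly)

    switching to the limit forms ``Na = ka t exp(-ka t)`` when ``ka ~= kd``.
    """
    if t < 0:
        raise ValueError(f"time must be nonnegative, got t={t}")
    ka, kd = rates.ka, rates.kd
    ns = math.exp(-ka * t)
    if rates.is_degenerate:
        na = ka * t * ns
        nd = 1.0 - ns - na
        return PopulationState(ns, na, nd)
    pref = ka / (kd - ka)
    ekd = math.exp(-kd * t)
    na = pref * (ns - ekd)
    nd = pref * ekd - kd / (kd - ka) * ns + 1.0
    return PopulationState(ns, na, nd)


def time_of_max_admitted(rates: RateSet) -> float:
    """Time (days) at which the admitted census ``Na`` peaks.

    ``t = ln(kd/ka) / (kd - ka)``, with the limit ``1/ka`` at equal rates.
    This is also ``t1``, the saturation time of the capacity-limited model.
    """
    if rates.is_degenerate:
        return 1.0 / rates.ka
    return math.log(rates.kd / rates.ka) / (rates.kd - rates.ka)


def max_admitted_fraction(rates: RateSet) -> float:
    """Peak admitted fraction ``Na^max`` (the kinetic surge capacity).

    A function of the rates only — the model derives the saturation census
    from the kinetics rather than from a bed count.  Equals ``1/e`` in the
    equal-rates limit.
    """
    if rates.is_degenerate:
        return math.exp(-1.0)
    return simple_model_at(time_of_max_admitted(rates), rates).Na


def delayed_model_at(t: float, rates: DelayedRateSet) -> DelayedPopulationState:
    """Evaluate the delayed-surge model at time ``t`` (days).

    Four-compartment Bateman chain with ``Ne(0) = 1``.  Raises
    :class:`DegenerateRatesError` when any two rates coincide (no limit
    forms are provided for this variant).
    """
    if t < 0:
        raise ValueError(f"time must be nonnegative, got t={t}")
    rates.require_distinct()
    ks, ka, kd = rates.ks, rates.ka, rates.kd
    es = math.exp(-ks * t)
    ea = math.exp(-ka * t)
    ed = math.exp(-kd * t)
    ne = es
    ns = ks / (ka - ks) * (es - ea)
    pref = ka * ks / (ka - ks)
    na = pref * (es / (kd - ks) - ea / (kd - ka) - (1.0 / (kd - ks) - 1.0 / (kd - ka)) * ed)
    nd = (
        pref
        * kd
        * (
            (ea - 1.0) / (ka * (kd - ka))
            - (es - 1.0) / (ks * (kd - ks))
            + (1.0 / (kd - ks) - 1.0 / (kd - ka)) * (ed - 1.0) / kd
        )
    )
    return DelayedPopulationState(ne, ns, na, nd)


def time_of_max_surge_delayed(rates: DelayedRateSet) -> float:
    """Time (days) at which the delayed surge ``Ns`` peaks:
    ``ln(ka/ks)/(ka - ks)``, with limit ``1/ka`` at ``ks ~= ka``."""
    if _is_close(rates.ks, rates.ka):
        return 1.0 / rates.ka
    return math.log(rates.ka / rates.ks) / (rates.ka - rates.ks)
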