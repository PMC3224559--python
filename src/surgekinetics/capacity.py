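"""Single-center maximum-capacity model.

The unconstrained kinetics hold only until the admitted census reaches the
center's kinetic surge capacity ``Na^max`` at time ``t1``.  From then until
the surge queue vanishes at ``t2`` the center is saturated and runs at a
zeroth-order throughput ``k'`` (one admission per discharge), after which
discharges relax exponentially at the pre-event rate ``kd``:

    region I   (0 <= t < t1):  unconstrained exponential kinetics
    region II  (t1 <= t < t2): Ns declines linearly at rate k', Na constant
    region III (t >= t2):      Ns = 0, Na decays as exp(-kd (t - t2))

``t99`` — the time at which 99% (or any chosen threshold) of the cohort has
been discharged — has a closed form in region III.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.optimize import brentq

from .core import PopulationState, RateSet, max_admitted_fraction, simple_model_at, time_of_max_admitted

__all__ = [
    "CapacityTimescales",
    "CapacityBoundaryState",
    "capacity_breakpoints",
    "capacity_boundary_state",
    "capacity_model_at",
    "capacity_t99",
]


@dataclass(frozen=True)
class CapacityTimescales:
    """Breakpoint times (days) of the capacity-limited model."""

    t1: float
    t2: float
    t99: float = math.nan

    def __post_init__(self) -> None:
        if not 0 < self.t1 < self.t2:
            raise ValueError(f"breakpoints must satisfy 0 < t1 < t2, got t1={self.t1}, t2={self.t2}")
        if not math.isnan(self.t99) and not self.t99 > self.t2:
            raise ValueError(f"t99={self.t99} must exceed t2={self.t2}")


@dataclass(frozen=True)
class CapacityBoundaryState:
    """Population fractions at the region boundaries t1 and t2.

    The admitted census is constant at ``Na^max`` throughout region II, so
    ``Na_t1 == Na_t2``.
    """

    Ns_t1: float
    Na_t1: float
    Nd_t1: float
    Ns_t2: float
    Na_t2: float
    Nd_t2: float


def capacity_breakpoints(rates: RateSet) -> CapacityTimescales:
    """Saturation time ``t1`` and queue-exhaustion time ``t2``.

    ``t1`` is the unconstrained argmax of ``Na``; ``t2 = t1 + Ns(t1)/k'``
    is the t-intercept of the linear region-II decline of the queue.
    """
    _require_k_prime(rates)
    t1 = time_of_max_admitted(rates)
    ns_t1 = math.exp(-rates.ka * t1)
    return CapacityTimescales(t1=t1, t2=t1 + ns_t1 / rates.k_prime)


def capacity_boundary_state(rates: RateSet) -> CapacityBoundaryState:
    """Populations at ``t1`` and ``t2`` (region II is linear in between)."""
    t1 = time_of_max_admitted(rates)
    ns1, na1, nd1 = simple_model_at(t1, rates)
    # Region II drains the whole queue into discharges: Nd_t2 = Nd_t1 + Ns_t1.
    return CapacityBoundaryState(
        Ns_t1=ns1, Na_t1=na1, Nd_t1=nd1,
        Ns_t2=0.0, Na_t2=na1, Nd_t2=nd1 + ns1,
    )


def capacity_model_at(t: float, rates: RateSet) -> tuple[PopulationState, str]:
    """Evaluate the piecewise model at time ``t`` (days).

    Returns the population fractions together with the region label
    ``"I"``, ``"II"`` or ``"III"`` (half-open membership ``[0,t1)``,
    ``[t1,t2)``, ``[t2,inf)``).  The zeroth-order region-II queue is
    clamped at zero exactly at the analytic ``t2``.
    """
    if t < 0:
        raise ValueError(f"time must be nonnegative, got t={t}")
    _require_k_prime(rates)
    ts = capacity_breakpoints(rates)
    if t < ts.t1:
        return simple_model_at(t, rates), "I"
    b = capacity_boundary_state(rates)
    if t < ts.t2:
        dt = t - ts.t1
        ns = max(b.Ns_t1 - rates.k_prime * dt, 0.0)
        return PopulationState(ns, b.Na_t1, b.Nd_t1 + rates.k_prime * dt), "II"
    decay = math.exp(-rates.kd * (t - ts.t2))
    na = b.Na_t2 * decay
    nd = b.Nd_t2 + b.Na_t2 * (1.0 - decay)
    return PopulationState(0.0, na, nd), "III"


def capacity_t99(rates: RateSet, threshold: float = 0.99) -> float:
    """Time (days) at which the discharged fraction reaches ``threshold``.

    Closed form in region III:

        t99 = t2 - (1/kd) ln(1 - (threshold - Nd_t2) / Na_t2)

    If the threshold is already reached before ``t2`` (possible only for
    thresholds below the model's ``Nd_t2``) the root is bracketed
    numerically in regions I/II instead, with a warning.
    """
    _require_k_prime(rates)
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    ts = capacity_breakpoints(rates)
    b = capacity_boundary_state(rates)
    if threshold == b.Nd_t2:
        return ts.t2
    if threshold < b.Nd_t2:
        warnings.warn(
            f"discharge threshold {threshold} is reached before the queue is exhausted "
            f"(Nd(t2) = {b.Nd_t2:.4f}); solving numerically in regions I/II",
            stacklevel=2,
        )
        return brentq(lambda t: capacity_model_at(t, rates)[0].Nd - threshold, 0.0, ts.t2, xtol=1e-12)
    return ts.t2 - math.log(1.0 - (threshold - b.Nd_t2) / b.Na_t2) / rates.kd


def _require_k_prime(rates: RateSet) -> None:
    if math.isnan(rates.k_prime):
        raise ValueError("the capacity model requires RateSet.k_prime (at-capacity throughput rate)")
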