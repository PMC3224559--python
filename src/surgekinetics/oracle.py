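"""Independent fixed-step numeric integration of the governing ODEs.

Every model in this package is a piecewise-linear ODE system whose
regime-switch times are known in closed form.  This module integrates the
governing equations directly with a classical fixed-step 4th-order
Runge-Kutta scheme, restarting exactly at each analytic breakpoint (exact
restarts eliminate event-location error), and serves as the brute-force
verification surface for the closed-form modules.  It is deliberately
simple: no adaptivity, no reuse of the closed-form solutions beyond the
breakpoint times themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import DelayedRateSet, RateSet
from .capacity import capacity_breakpoints
from .mortality import DeathRateSet, mortality_boundaries
from .ptc import PTCRateSet, ptc_boundaries, ptc_t2

__all__ = [
    "OdeSpec",
    "integrate",
    "simple_ode",
    "delayed_ode",
    "capacity_ode",
    "ptc_ode",
    "mortality_ode",
]

RHS = Callable[[float, np.ndarray], np.ndarray]


@dataclass
class OdeSpec:
    """Piecewise ODE system: compartment names, (start_time, rhs) segments
    in increasing start order (first at t = 0), and the initial state."""

    names: tuple[str, ...]
    segments: list[tuple[float, RHS]]
    y0: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        starts = [s for s, _ in self.segments]
        if not starts or starts[0] != 0.0 or sorted(starts) != starts:
            raise ValueError("segments must start at t=0 and be sorted by start time")
        self.y0 = np.asarray(self.y0, dtype=float)

    def rhs_at(self, t: float) -> RHS:
        rhs = self.segments[0][1]
        for start, f in self.segments:
            if t >= start:
                rhs = f
        return rhs


def integrate(spec: OdeSpec, t_grid: Sequence[float], step: float = 1e-4) -> np.ndarray:
    """Integrate ``spec`` and return states at ``t_grid`` (sorted, >= 0).

    Classical RK4 with uniform substeps of at most ``step`` days inside
    each interval between consecutive knots (breakpoints and output
    times), so every breakpoint and output time is hit exactly.  Raises if
    any population drops below -1e-8 (a region/RHS mismatch).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0:
        raise ValueError("t_grid must be a nonempty 1-D sequence")
    if np.any(np.diff(t_grid) < 0) or t_grid[0] < 0:
        raise ValueError("t_grid must be sorted and nonnegative")
    if step <= 0:
        raise ValueError("step must be positive")

    breakpoints = [s for s, _ in spec.segments if s > 0]
    knots = np.unique(np.concatenate([[0.0], breakpoints, t_grid]))
    knots = knots[knots <= t_grid[-1] + 1e-300]

    out = np.empty((len(t_grid), len(spec.y0)))
    y = spec.y0.copy()
    want = {float(t) for t in t_grid}
    idx = 0
    if knots[0] in want:
        while idx < len(t_grid) and t_grid[idx] == knots[0]:
            out[idx] = y
            idx += 1
    for a, b in zip(knots[:-1], knots[1:]):
        rhs = spec.rhs_at(0.5 * (a + b))  # segment containing (a, b)
        n = max(1, int(np.ceil((b - a) / step)))
        h = (b - a) / n
        t = a
        for _ in range(n):
            k1 = rhs(t, y)
            k2 = rhs(t + 0.5 * h, y + 0.5 * h * k1)
            k3 = rhs(t + 0.5 * h, y + 0.5 * h * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += h
        if np.any(y < -1e-8):
            raise RuntimeError(
                f"negative population at t={b:.6g}: {dict(zip(spec.names, y))} "
                "(region/RHS mismatch?)"
            )
        while idx < len(t_grid) and t_grid[idx] <= b:
            out[idx] = y
            idx += 1
    return out


def simple_ode(rates: RateSet) -> OdeSpec:
    """Unconstrained three-compartment chain."""
    ka, kd = rates.ka, rates.kd

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        ns, na, _ = y
        return np.array([-ka * ns, ka * ns - kd * na, kd * na])

    return OdeSpec(("Ns", "Na", "Nd"), [(0.0, rhs)], np.array([1.0, 0.0, 0.0]))


def delayed_ode(rates: DelayedRateSet) -> OdeSpec:
    """Four-compartment delayed-surge chain."""
    ks, ka, kd = rates.ks, rates.ka, rates.kd

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        ne, ns, na, _ = y
        return np.array([-ks * ne, ks * ne - ka * ns, ka * ns - kd * na, kd * na])

    return OdeSpec(("Ne", "Ns", "Na", "Nd"), [(0.0, rhs)], np.array([1.0, 0.0, 0.0, 0.0]))


def capacity_ode(rates: RateSet) -> OdeSpec:
    """Single-center capacity model with its two analytic breakpoints."""
    ka, kd, kp = rates.ka, rates.kd, rates.k_prime
    ts = capacity_breakpoints(rates)

    def rhs1(t: float, y: np.ndarray) -> np.ndarray:
        ns, na, _ = y
        return np.array([-ka * ns, ka * ns - kd * na, kd * na])

    def rhs2(t: float, y: np.ndarray) -> np.ndarray:
        return np.array([-kp, 0.0, kp])

    def rhs3(t: float, y: np.ndarray) -> np.ndarray:
        _, na, _ = y
        return np.array([0.0, -kd * na, kd * na])

    return OdeSpec(("Ns", "Na", "Nd"),
                   [(0.0, rhs1), (ts.t1, rhs2), (ts.t2, rhs3)],
                   np.array([1.0, 0.0, 0.0]))


def _dedupe(segments: list[tuple[float, RHS]]) -> list[tuple[float, RHS]]:
    # zero-width regimes (e.g. the symmetric-rates case, t1p == t1a): keep
    # the later region's RHS at a duplicated start time
    out: list[tuple[float, RHS]] = []
    for start, f in segments:
        if out and out[-1][0] == start:
            out[-1] = (start, f)
        else:
            out.append((start, f))
    return out


def ptc_ode(rates: PTCRateSet) -> OdeSpec:
    """Two-center pediatric-cohort model (valid adult-faster orientation)."""
    t1a, t1p, _ = ptc_boundaries(rates)
    t2 = ptc_t2(rates)
    kpaa, kpda, kpap, kpdp = rates.kpaa, rates.kpda, rates.kpap, rates.kpdp
    kap, kappa, k = rates.ka_prime, rates.kappa, rates.k

    def rhs1(t: float, y: np.ndarray) -> np.ndarray:
        ps, paa, pap, _ = y
        return np.array([-k * ps, kpaa * ps - kpda * paa, kpap * ps - kpdp * pap,
                         kpda * paa + kpdp * pap])

    def rhs2(t: float, y: np.ndarray) -> np.ndarray:
        ps, _, pap, _ = y
        return np.array([-kap - kpap * ps, 0.0, kpap * ps - kpdp * pap, kap + kpdp * pap])

    def rhs3(t: float, y: np.ndarray) -> np.ndarray:
        return np.array([-kappa, 0.0, 0.0, kappa])

    def rhs4(t: float, y: np.ndarray) -> np.ndarray:
        _, paa, pap, _ = y
        return np.array([0.0, -kpda * paa, -kpdp * pap, kpda * paa + kpdp * pap])

    segs = _dedupe([(0.0, rhs1), (t1a, rhs2), (t1p, rhs3), (t2, rhs4)])
    return OdeSpec(("Ps", "Paa", "Pap", "Pd"), segs, np.array([1.0, 0.0, 0.0, 0.0]))


def mortality_ode(rates: PTCRateSet, deaths: DeathRateSet) -> OdeSpec:
    """Five-compartment death-rate model (valid adult-faster orientation)."""
    t1a, t1p, t2, _ = mortality_boundaries(rates, deaths)
    kpaa, kpda, kpap, kpdp = rates.kpaa, rates.kpda, rates.kpap, rates.kpdp
    kap, kappa, k = rates.ka_prime, rates.kappa, rates.k
    ws, wa, wp, wd = deaths.omega_s, deaths.omega_a, deaths.omega_p, deaths.omega_d
    wap, wpp = deaths.omega_a_prime, deaths.omega_p_prime
    mu = kappa + wap + (0.0 if rates.ptc_inactive else wpp)

    def rhs1(t: float, y: np.ndarray) -> np.ndarray:
        ps, paa, pap, pd, _ = y
        return np.array([
            -(k + ws) * ps,
            kpaa * ps - (kpda + wa) * paa,
            kpap * ps - (kpdp + wp) * pap,
            kpda * paa + kpdp * pap - wd * pd,
            ws * ps + wa * paa + wp * pap + wd * pd,
        ])

    def rhs2(t: float, y: np.ndarray) -> np.ndarray:
        ps, _, pap, pd, _ = y
        return np.array([
            -(kpap + ws) * ps - (kap + wap),
            0.0,
            kpap * ps - (kpdp + wp) * pap,
            kpdp * pap + kap - wd * pd,
            ws * ps + wap + wp * pap + wd * pd,
        ])

    def rhs3(t: float, y: np.ndarray) -> np.ndarray:
        ps, _, _, pd, _ = y
        return np.array([-ws * ps - mu, 0.0, 0.0, kappa - wd * pd,
                         ws * ps + wd * pd + wap + wpp])

    def rhs4(t: float, y: np.ndarray) -> np.ndarray:
        _, paa, pap, pd, _ = y
        return np.array([0.0, -(kpda + wa) * paa, -(kpdp + wp) * pap,
                         kpda * paa + kpdp * pap - wd * pd,
                         wa * paa + wp * pap + wd * pd])

    segs = _dedupe([(0.0, rhs1), (t1a, rhs2), (t1p, rhs3), (t2, rhs4)])
    return OdeSpec(("Ps", "Paa", "Pap", "Pd", "PD"), segs, np.array([1.0, 0.0, 0.0, 0.0, 0.0]))
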