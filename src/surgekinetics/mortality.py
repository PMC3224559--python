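"""Two-center capacity model with explicit per-compartment death rates.

Extends the PTC model with a deceased compartment ``PD`` fed by death
rates ``omega`` (day^-1) from each living compartment: the untreated
surge (``omega_s``), inpatients at the adult center (``omega_a``) and the
PTC (``omega_p``), and discharged patients (``omega_d``, the background
population rate).  While a center runs at capacity its census is held
constant by backfilling from the surge, so inpatient deaths during that
phase (rates ``omega_a'``, ``omega_p'``) appear as constant flows into
``PD``.

The piecewise closed forms mirror the death-free model, with the
compartment decay rates replaced by composite constants

    lambda_s = k + omega_s          lambda_a  = kpda + omega_a
    lambda_p = kpdp + omega_p       lambda_II = kpap + omega_s
    lambda_a' = ka' + omega_a'      mu = kappa + omega_a' + omega_p'

All five compartments sum to 1 in every region; ``PD`` is nondecreasing.
The headline outcome measure is the deceased fraction at a fixed
evaluation time (10 days in the historical scenario).

The "no PTC" comparator is this same model with ``kpap = kp' = 0``: the
PTC never fills, the adult-center at-capacity regime lasts until the
surge is exhausted, and the PTC regions are skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

from .core import DEGENERACY_RTOL, DegenerateRatesError
from .ptc import PediatricFasterError, PTCRateSet

__all__ = [
    "DeathRateSet",
    "MortalityBoundaryConstants",
    "MortalityState",
    "mortality_boundaries",
    "mortality_model_at",
    "deceased_fraction",
    "mortality_risk_reduction",
]


@dataclass(frozen=True)
class DeathRateSet:
    """Per-compartment death rates (day^-1).

    ``omega_a_prime``/``omega_p_prime`` are the inpatient death rates while
    the centers run at capacity; they default to the pre-capacity inpatient
    rates (no basis for a steady-state distinction).
    """

    omega_s: float
    omega_a: float
    omega_p: float
    omega_d: float
    omega_a_prime: float = math.nan
    omega_p_prime: float = math.nan

    def __post_init__(self) -> None:
        for name in ("omega_s", "omega_a", "omega_p", "omega_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if math.isnan(self.omega_a_prime):
            object.__setattr__(self, "omega_a_prime", self.omega_a)
        if math.isnan(self.omega_p_prime):
            object.__setattr__(self, "omega_p_prime", self.omega_p)
        if self.omega_a_prime < 0 or self.omega_p_prime < 0:
            raise ValueError("steady-state death rates must be nonnegative")

    @classmethod
    def zero(cls) -> "DeathRateSet":
        return cls(0.0, 0.0, 0.0, 0.0)

    def relabeled(self) -> "DeathRateSet":
        """Swap the two centers' inpatient death rates."""
        return replace(self, omega_a=self.omega_p, omega_p=self.omega_a,
                       omega_a_prime=self.omega_p_prime, omega_p_prime=self.omega_a_prime)


class MortalityState(NamedTuple):
    """Five-compartment fractions (living + deceased sum to 1)."""

    Ps: float
    Paa: float
    Pap: float
    Pd: float
    PD: float


@dataclass(frozen=True)
class MortalityBoundaryConstants:
    """Boundary values and integration constants of the piecewise solution.

    ``A, C, H, E, J`` — compartment values at t1a; ``alpha_prime, rho,
    theta, phi, Gamma, Delta, Lam`` — region-II constants; ``B, D, F, K``
    — values at t1p; ``G, L`` — discharged/deceased fractions at t2.
    ``J <= K <= L`` since the deceased fraction is nondecreasing.
    """

    A: float
    C: float
    H: float
    E: float
    J: float
    alpha_prime: float
    rho: float
    theta: float
    phi: float
    Gamma: float
    Delta: float
    Lam: float
    B: float
    D: float
    F: float
    K: float
    G: float
    L: float


def _iexp(r: float, dt: float) -> float:
    """Integral of exp(-r u) du on [0, dt]; exact at r = 0 and stable for small r."""
    if r == 0.0:
        return dt
    return -math.expm1(-r * dt) / r


def _check_distinct(pairs) -> None:
    for n1, v1, n2, v2 in pairs:
        if abs(v1 - v2) <= DEGENERACY_RTOL * max(abs(v1), abs(v2)):
            raise DegenerateRatesError(
                f"closed form is singular at {n1} == {n2} (= {v1}); no limit form implemented"
            )


@dataclass(frozen=True)
class _MortSolution:
    rates: PTCRateSet
    deaths: DeathRateSet
    t1a: float
    t1p: float
    t2: float
    c: MortalityBoundaryConstants
    relabeled: bool
    # composite rates
    lam_s: float
    lam_a: float
    lam_p: float
    lam_ii: float
    lam_ap: float
    mu: float


def _region1_state(t: float, rates: PTCRateSet, deaths: DeathRateSet,
                   lam_s: float, lam_a: float, lam_p: float) -> MortalityState:
    wd = deaths.omega_d
    a1 = rates.kpaa / (lam_a - lam_s)
    p1 = rates.kpap / (lam_p - lam_s) if rates.kpap > 0 else 0.0
    es, ea = math.exp(-lam_s * t), math.exp(-lam_a * t)
    ep = math.exp(-lam_p * t) if rates.kpap > 0 else 0.0
    ps = es
    paa = a1 * (es - ea)
    pap = p1 * (es - ep) if rates.kpap > 0 else 0.0
    # Pd: inhomogeneous relaxation toward the discharged pool (decay omega_d)
    cs = (rates.kpda * a1 + rates.kpdp * p1) / (wd - lam_s)
    ca = -rates.kpda * a1 / (wd - lam_a)
    cp = -rates.kpdp * p1 / (wd - lam_p) if rates.kpap > 0 else 0.0
    cd = -(cs + ca + cp)
    ed = math.exp(-wd * t)
    pd = cs * es + ca * ea + cp * ep + cd * ed
    # PD: integral of the death flows out of every living compartment
    ws, wa, wp = deaths.omega_s, deaths.omega_a, deaths.omega_p
    pdd = (
        (ws + wa * a1 + wp * p1 + wd * cs) * _iexp(lam_s, t)
        + (-wa * a1 + wd * ca) * _iexp(lam_a, t)
        + (-wp * p1 + wd * cp) * (_iexp(lam_p, t) if rates.kpap > 0 else 0.0)
        + wd * cd * _iexp(wd, t)
    )
    return MortalityState(ps, paa, pap, pd, pdd)


def _solve_oriented(rates: PTCRateSet, deaths: DeathRateSet) -> _MortSolution:
    k = rates.k
    ws, wd = deaths.omega_s, deaths.omega_d
    lam_s = k + ws
    lam_a = rates.kpda + deaths.omega_a
    lam_p = rates.kpdp + deaths.omega_p
    lam_ii = rates.kpap + ws
    lam_ap = rates.ka_prime + deaths.omega_a_prime

    _check_distinct((("lambda_a", lam_a, "lambda_s", lam_s),
                     ("omega_d", wd, "lambda_s", lam_s),
                     ("omega_d", wd, "lambda_a", lam_a)))
    if rates.kpap > 0:
        _check_distinct((("lambda_p", lam_p, "lambda_s", lam_s),
                         ("omega_d", wd, "lambda_p", lam_p),
                         ("lambda_p", lam_p, "lambda_II", lam_ii),
                         ("omega_d", wd, "lambda_II", lam_ii)))

    t1a = math.log(lam_s / lam_a) / (lam_s - lam_a)
    A, C, H, E, J = _region1_state(t1a, rates, deaths, lam_s, lam_a, lam_p)

    if rates.ptc_inactive:
        # Terminal at-capacity regime: the queue drains until Ps = 0.
        # Ps = alpha' e^{-omega_s dt} - rho with rho = lambda_a'/omega_s
        # (linear decline at rate lambda_a' in the omega_s -> 0 limit).
        mu = rates.ka_prime + deaths.omega_a_prime  # no PTC inpatients exist
        if ws > 0:
            dt2 = math.log1p(A * ws / lam_ap) / ws
        else:
            dt2 = A / lam_ap
        t2 = t1a + dt2
        # Pd and PD across the terminal regime (theta = phi = H = 0).
        pd_t2 = E * math.exp(-wd * dt2) + rates.ka_prime * _iexp(wd, dt2)
        pdd_t2 = J + (A * ws + lam_ap) * _iexp(ws, dt2) + (wd * E - rates.ka_prime) * _iexp(wd, dt2)
        c = MortalityBoundaryConstants(
            A=A, C=C, H=0.0, E=E, J=J,
            alpha_prime=math.nan, rho=math.nan, theta=0.0, phi=0.0,
            Gamma=math.nan, Delta=math.nan, Lam=math.nan,
            B=0.0, D=0.0, F=pd_t2, K=pdd_t2, G=pd_t2, L=pdd_t2,
        )
        return _MortSolution(rates, deaths, t1a, t2, t2, c, False,
                             lam_s, lam_a, lam_p, lam_ii, lam_ap, mu)

    mu = rates.kappa + deaths.omega_a_prime + deaths.omega_p_prime
    rho = lam_ap / lam_ii
    alpha_p = A + rho
    theta = rates.kpap * alpha_p / (lam_p - lam_ii)
    phi = rates.kpap * rho / lam_p
    # t1p: argmax of region-II Pap = (H + phi - theta) e^{-lam_p dt}
    #      + theta e^{-lam_II dt} - phi
    chi = H + phi - theta
    arg = -(lam_p * chi) / (lam_ii * theta)
    if arg <= 0.0:
        raise ValueError(
            "PTC saturation time is undefined for these rates: the log argument "
            f"-lambda_p*(H+phi-theta)/(lambda_II*theta) = {arg:.3e} is nonpositive"
        )
    dt1 = math.log(arg) / (lam_p - lam_ii)
    if dt1 < 0.0:
        if dt1 < -1e-6 * max(t1a, 1.0):
            raise RuntimeError(
                f"inconsistent region-II maximum (offset {dt1:.3e} d before t1a); "
                "check the adult-faster orientation of the rates"
            )
        dt1 = 0.0
    t1p = t1a + dt1

    gam = chi * rates.kpdp / (wd - lam_p)
    dlt = theta * rates.kpdp / (wd - lam_ii)
    pd_flow = rates.ka_prime - rates.kpdp * phi  # constant discharge inflow in region II

    e_ii = math.exp(-lam_ii * dt1)
    e_p = math.exp(-lam_p * dt1)
    e_d = math.exp(-wd * dt1)
    B = alpha_p * e_ii - rho
    D = chi * e_p + theta * e_ii - phi
    F = gam * (e_p - e_d) + dlt * (e_ii - e_d) + pd_flow * _iexp(wd, dt1) + E * e_d
    # Linear death inflow in region II: adult at-capacity deaths plus the
    # constant parts of omega_s*Ps, omega_p*Pap and omega_d*Pd.  pd_flow is
    # included unconditionally: at omega_d = 0 the (wd*(...) - pd_flow)
    # integral below contributes -pd_flow*dt and cancels it exactly.
    wa_p, wp_ = deaths.omega_a_prime, deaths.omega_p
    lin = wa_p - ws * rho - wp_ * phi + pd_flow
    K = (
        J
        + lin * dt1
        + (ws * alpha_p + wp_ * theta + wd * dlt) * _iexp(lam_ii, dt1)
        + (wp_ * chi + wd * gam) * _iexp(lam_p, dt1)
        + (wd * (E - gam - dlt) - pd_flow) * _iexp(wd, dt1)
    )

    # Region III: queue drains at composite rate mu with surge attrition omega_s.
    if ws > 0:
        dt2 = math.log1p(B * ws / mu) / ws
    else:
        dt2 = B / mu
    t2 = t1p + dt2
    G = F * math.exp(-wd * dt2) + rates.kappa * _iexp(wd, dt2)
    L = K + (B * ws + mu) * _iexp(ws, dt2) + (wd * F - rates.kappa) * _iexp(wd, dt2)

    c = MortalityBoundaryConstants(A=A, C=C, H=H, E=E, J=J, alpha_prime=alpha_p,
                                   rho=rho, theta=theta, phi=phi, Gamma=gam,
                                   Delta=dlt, Lam=math.nan if wd == 0 else pd_flow / wd,
                                   B=B, D=D, F=F, K=K, G=G, L=L)
    return _MortSolution(rates, deaths, t1a, t1p, t2, c, False,
                         lam_s, lam_a, lam_p, lam_ii, lam_ap, mu)


def _msolve(rates: PTCRateSet, deaths: DeathRateSet, allow_relabel: bool = False) -> _MortSolution:
    lam_a = rates.kpda + deaths.omega_a
    lam_p = rates.kpdp + deaths.omega_p
    if rates.ptc_inactive or lam_p <= lam_a * (1.0 + DEGENERACY_RTOL):
        return _solve_oriented(rates, deaths)
    if not allow_relabel:
        raise PediatricFasterError(
            f"kpdp+omega_p={lam_p} > kpda+omega_a={lam_a}: the PTC saturates before the "
            "adult center. Relabel the centers' rates or pass allow_relabel=True."
        )
    sol = _solve_oriented(rates.relabeled(), deaths.relabeled())
    return replace(sol, relabeled=True)


def mortality_boundaries(rates: PTCRateSet, deaths: DeathRateSet,
                         allow_relabel: bool = False) -> tuple[float, float, float, MortalityBoundaryConstants]:
    """Breakpoints ``(t1a, t1p, t2)`` (physical labels) and all boundary
    constants of the death-rate model.  With the PTC inactive
    (``kpap = kp' = 0``) the at-capacity regime is terminal and
    ``t1p == t2``."""
    sol = _msolve(rates, deaths, allow_relabel)
    t1a, t1p = (sol.t1p, sol.t1a) if sol.relabeled else (sol.t1a, sol.t1p)
    return t1a, t1p, sol.t2, sol.c


def _state_oriented(t: float, sol: _MortSolution) -> tuple[MortalityState, str]:
    rates, deaths, c = sol.rates, sol.deaths, sol.c
    ws, wd = deaths.omega_s, deaths.omega_d
    if t < sol.t1a:
        return _region1_state(t, rates, deaths, sol.lam_s, sol.lam_a, sol.lam_p), "I"
    if rates.ptc_inactive:
        if t < sol.t2:
            dt = t - sol.t1a
            ps = max(c.A * math.exp(-ws * dt) - sol.lam_ap * _iexp(ws, dt), 0.0)
            pd = c.E * math.exp(-wd * dt) + rates.ka_prime * _iexp(wd, dt)
            pdd = c.J + (c.A * ws + sol.lam_ap) * _iexp(ws, dt) + (wd * c.E - rates.ka_prime) * _iexp(wd, dt)
            return MortalityState(ps, c.C, 0.0, pd, pdd), "II"
        return _region4_state(t - sol.t2, sol), "IV"
    if t < sol.t1p:
        dt = t - sol.t1a
        e_ii = math.exp(-sol.lam_ii * dt)
        e_p = math.exp(-sol.lam_p * dt)
        e_d = math.exp(-wd * dt)
        chi = c.H + c.phi - c.theta
        pd_flow = rates.ka_prime - rates.kpdp * c.phi
        ps = c.alpha_prime * e_ii - c.rho
        pap = chi * e_p + c.theta * e_ii - c.phi
        pd = c.Gamma * (e_p - e_d) + c.Delta * (e_ii - e_d) + pd_flow * _iexp(wd, dt) + c.E * e_d
        lin = deaths.omega_a_prime - ws * c.rho - deaths.omega_p * c.phi + pd_flow
        pdd = (
            c.J
            + lin * dt
            + (ws * c.alpha_prime + deaths.omega_p * c.theta + wd * c.Delta) * _iexp(sol.lam_ii, dt)
            + (deaths.omega_p * chi + wd * c.Gamma) * _iexp(sol.lam_p, dt)
            + (wd * (c.E - c.Gamma - c.Delta) - pd_flow) * _iexp(wd, dt)
        )
        return MortalityState(ps, c.C, pap, pd, pdd), "II"
    if t < sol.t2:
        dt = t - sol.t1p
        ps = max(c.B * math.exp(-ws * dt) - sol.mu * _iexp(ws, dt), 0.0)
        pd = c.F * math.exp(-wd * dt) + rates.kappa * _iexp(wd, dt)
        pdd = c.K + (c.B * ws + sol.mu) * _iexp(ws, dt) + (wd * c.F - rates.kappa) * _iexp(wd, dt)
        return MortalityState(ps, c.C, c.D, pd, pdd), "III"
    return _region4_state(t - sol.t2, sol), "IV"


def _region4_state(dt: float, sol: _MortSolution) -> MortalityState:
    rates, deaths, c = sol.rates, sol.deaths, sol.c
    wd = deaths.omega_d
    e_a = math.exp(-sol.lam_a * dt)
    e_p = math.exp(-sol.lam_p * dt) if rates.kpap > 0 else 0.0
    e_d = math.exp(-wd * dt)
    paa = c.C * e_a
    pap = c.D * e_p
    ca = rates.kpda * c.C / (wd - sol.lam_a)
    cp = rates.kpdp * c.D / (wd - sol.lam_p) if rates.kpap > 0 else 0.0
    pd = ca * (e_a - e_d) + cp * (e_p - e_d) + c.G * e_d
    pdd = (
        c.L
        + (deaths.omega_a * c.C + wd * ca) * _iexp(sol.lam_a, dt)
        + (deaths.omega_p * c.D + wd * cp) * _iexp(sol.lam_p, dt)
        + wd * (c.G - ca - cp) * _iexp(wd, dt)
    )
    return MortalityState(0.0, paa, pap, pd, pdd)


def mortality_model_at(t: float, rates: PTCRateSet, deaths: DeathRateSet,
                       allow_relabel: bool = False) -> tuple[MortalityState, str]:
    """Evaluate the five-compartment model at time ``t`` (days); returns
    the state (physical compartment labels) and the region label."""
    if t < 0:
        raise ValueError(f"time must be nonnegative, got t={t}")
    sol = _msolve(rates, deaths, allow_relabel)
    state, region = _state_oriented(t, sol)
    if sol.relabeled:
        state = MortalityState(state.Ps, state.Pap, state.Paa, state.Pd, state.PD)
    return state, region


def deceased_fraction(rates: PTCRateSet, deaths: DeathRateSet, t_eval: float,
                      allow_relabel: bool = False) -> float:
    """Fraction of the initial cohort deceased at ``t_eval`` days."""
    return mortality_model_at(t_eval, rates, deaths, allow_relabel)[0].PD


def mortality_risk_reduction(rates_no_ptc: PTCRateSet, rates_ptc: PTCRateSet,
                             deaths: DeathRateSet, t_eval: float) -> tuple[float, float]:
    """Absolute and relative mortality-risk reduction conferred by the PTC.

    ``absolute = PD_noPTC - PD_PTC``; ``relative = absolute / PD_noPTC``
    (reported as 0 when the no-PTC mortality is itself 0).
    """
    pd_no = deceased_fraction(rates_no_ptc, deaths, t_eval)
    pd_yes = deceased_fraction(rates_ptc, deaths, t_eval)
    absolute = pd_no - pd_yes
    relative = absolute / pd_no if pd_no > 0 else 0.0
    return absolute, relative
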