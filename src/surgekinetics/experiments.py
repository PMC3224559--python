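"""The package's computational experiments as reproducible procedures.

These wrap the model modules into the studies a disaster planner would
actually run on the historical baseline (the 2010 Haiti field-hospital
example): scanning a hypothetical PTC's speed relative to the fitted
adult center, locating the discharge-time ("trapping") peak, and the
mortality comparison between the no-PTC and PTC-available arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .capacity import capacity_t99
from .core import RateSet
from .fitting import FitObservations
from .mortality import DeathRateSet, deceased_fraction
from .ptc import PTCRateSet, ptc_timescales

__all__ = [
    "haiti_observations",
    "haiti_death_rates",
    "ptc_rates_from_adult",
    "no_ptc_rates",
    "ScaleScanResult",
    "scale_factor_scan",
    "find_t99_peak",
    "find_baseline_crossing",
    "MortalityComparison",
    "mortality_comparison",
]

SCAN_MODES = ("uniform", "fixed_discharge")


def haiti_observations() -> FitObservations:
    """Observed timescales of the IDF field hospital after the 2010 Haiti
    earthquake: saturation within 2 days, all 1111 patients treated in 10
    days, with the closure assumption tau = t99 - t2 = t1 = 2 days."""
    return FitObservations(t1_obs=2.0, t99_obs=10.0, tau=2.0)


def haiti_death_rates() -> DeathRateSet:
    """Literature death rates for the historical mortality scenario.

    In-hospital: 8.6%% of admitted patients over 15 days (1995
    Hanshin-Awaji earthquake), 0.086/15 per day.  Untreated surge: scaled
    by the Chi-Chi earthquake finding that 7%% of all fatalities died
    while hospitalized, i.e. (0.93/0.07) times the in-hospital rate.
    Discharged: the US background age-adjusted rate, 2e-5 per day.
    At-capacity inpatient rates equal the pre-capacity inpatient rates.
    """
    in_hospital = 0.086 / 15.0
    return DeathRateSet(
        omega_s=in_hospital * 0.93 / 0.07,
        omega_a=in_hospital,
        omega_p=in_hospital,
        omega_d=2e-5,
    )


def ptc_rates_from_adult(adult: RateSet, scale: float = 1.0, mode: str = "uniform") -> PTCRateSet:
    """Two-center rates with the PTC expressed relative to the fitted
    adult center.

    ``uniform`` scales all three PTC-side rates by ``scale``;
    ``fixed_discharge`` pins the PTC discharge rate at the adult value
    (kpdp = kpda) and scales only the admission and steady-state rates.
    """
    if mode not in SCAN_MODES:
        raise ValueError(f"mode must be one of {SCAN_MODES}, got {mode!r}")
    if not 0.0 < scale <= 1.0:
        raise ValueError(f"scale must lie in (0, 1], got {scale}")
    kpdp = adult.kd if mode == "fixed_discharge" else scale * adult.kd
    return PTCRateSet(
        kpaa=adult.ka, kpda=adult.kd,
        kpap=scale * adult.ka, kpdp=kpdp,
        ka_prime=adult.k_prime, kp_prime=scale * adult.k_prime,
    )


def no_ptc_rates(adult: RateSet) -> PTCRateSet:
    """Comparator arm with no PTC: the pediatric cohort sees only the
    adult center (kpap = kp' = 0)."""
    return PTCRateSet(kpaa=adult.ka, kpda=adult.kd, kpap=0.0, kpdp=adult.kd,
                      ka_prime=adult.k_prime, kp_prime=0.0)


@dataclass
class ScaleScanResult:
    """Timescales of the two-center model across PTC scale factors.

    ``errors`` records per-point boundary failures (scan continues)."""

    mode: str
    scale: np.ndarray
    t1a: np.ndarray
    t1p: np.ndarray
    t2: np.ndarray
    t99: np.ndarray
    baseline_t99: float
    adult_rates: RateSet
    threshold: float = 0.99
    errors: dict[float, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "scale": self.scale, "t1a_days": self.t1a, "t1p_days": self.t1p,
            "t2_days": self.t2, "t99_days": self.t99,
        })


def _scan_point(adult: RateSet, s: float, mode: str, threshold: float):
    ts = ptc_timescales(ptc_rates_from_adult(adult, s, mode), threshold=threshold)
    return ts.t1a, ts.t1p, ts.t2, ts.t99


def scale_factor_scan(adult_rates: RateSet, s_grid=None, mode: str = "uniform",
                      threshold: float = 0.99) -> ScaleScanResult:
    """Scan the PTC scale factor over a logarithmic grid (default 60
    points from 1e-3 to 0.999) and record the model timescales at each.
    """
    if mode not in SCAN_MODES:
        raise ValueError(f"mode must be one of {SCAN_MODES}, got {mode!r}")
    if s_grid is None:
        s_grid = np.geomspace(1e-3, 0.999, 60)
    s_grid = np.asarray(s_grid, dtype=float)
    out = np.full((4, len(s_grid)), np.nan)
    errors: dict[float, str] = {}
    for i, s in enumerate(s_grid):
        try:
            out[:, i] = _scan_point(adult_rates, float(s), mode, threshold)
        except (ValueError, RuntimeError) as exc:
            errors[float(s)] = str(exc)
    return ScaleScanResult(
        mode=mode, scale=s_grid, t1a=out[0], t1p=out[1], t2=out[2], t99=out[3],
        baseline_t99=capacity_t99(adult_rates, threshold),
        adult_rates=adult_rates, threshold=threshold, errors=errors,
    )


def find_t99_peak(scan: ScaleScanResult, refine_tol: float = 1e-4) -> float | None:
    """Scale factor at which ``t99`` attains its interior maximum.

    The coarse-grid argmax is refined by bounded golden-section search
    between its neighbouring grid points.  Returns ``None`` when the
    maximum sits on the grid boundary (no interior peak, e.g. the
    fixed-discharge mode where t99 decreases monotonically).
    """
    valid = np.isfinite(scan.t99)
    if valid.sum() < 3:
        raise ValueError("too few successful scan points to locate a peak")
    idx = np.where(valid)[0]
    best = idx[np.argmax(scan.t99[idx])]
    pos = np.where(idx == best)[0][0]
    if pos == 0 or pos == len(idx) - 1:
        return None
    lo, hi = scan.scale[idx[pos - 1]], scan.scale[idx[pos + 1]]
    res = minimize_scalar(
        lambda s: -_scan_point(scan.adult_rates, s, scan.mode, scan.threshold)[3],
        bounds=(lo, hi), method="bounded", options={"xatol": refine_tol},
    )
    return float(res.x)


def find_baseline_crossing(scan: ScaleScanResult) -> float | None:
    """Largest-scale downward crossing of ``t99`` through the no-PTC
    baseline value, refined by root bracketing; ``None`` if t99 never
    falls below the baseline on the grid."""
    idx = np.where(np.isfinite(scan.t99))[0]
    crossing = None
    for a, b in zip(idx[:-1], idx[1:]):
        fa = scan.t99[a] - scan.baseline_t99
        fb = scan.t99[b] - scan.baseline_t99
        if fa > 0 >= fb:
            crossing = brentq(
                lambda s: _scan_point(scan.adult_rates, s, scan.mode, scan.threshold)[3]
                - scan.baseline_t99,
                scan.scale[a], scan.scale[b], xtol=1e-6,
            )
    return None if crossing is None else float(crossing)


@dataclass(frozen=True)
class MortalityComparison:
    """Deceased fractions of both arms at ``t_eval`` and the mortality
    risk reductions conferred by the PTC.  ``relative_defined`` is False
    when the no-PTC arm has zero mortality (relative reported as 0)."""

    t_eval_days: float
    deceased_no_ptc: float
    deceased_ptc: float
    absolute_reduction: float
    relative_reduction: float
    relative_defined: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"arm": "no_ptc", "deceased_fraction": self.deceased_no_ptc},
            {"arm": "ptc", "deceased_fraction": self.deceased_ptc},
        ])


def mortality_comparison(adult_rates: RateSet, deaths: DeathRateSet | None = None,
                         t_eval: float = 10.0, ptc_scale: float = 1.0) -> MortalityComparison:
    """Deceased fraction at ``t_eval`` days without a PTC versus with a
    PTC running at ``ptc_scale`` times the adult center's rates (default:
    equal rates), under the death-rate model."""
    if deaths is None:
        deaths = haiti_death_rates()
    pd_no = deceased_fraction(no_ptc_rates(adult_rates), deaths, t_eval)
    pd_yes = deceased_fraction(ptc_rates_from_adult(adult_rates, ptc_scale), deaths, t_eval)
    absolute = pd_no - pd_yes
    defined = pd_no > 0
    return MortalityComparison(
        t_eval_days=t_eval,
        deceased_no_ptc=pd_no,
        deceased_ptc=pd_yes,
        absolute_reduction=absolute,
        relative_reduction=absolute / pd_no if defined else 0.0,
        relative_defined=defined,
    )
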