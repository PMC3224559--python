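"""Scenario configuration, validation and trajectory serialization.

A scenario is a flat, human-readable YAML document describing one model
variant and its inputs.  Rate keys carry their units in the name
(``*_per_day``) because unit slips are the main user hazard with this
kind of model.  Rates can be given directly, or — for the capacity-based
variants — derived by fitting the observed timescales in a ``fit`` block.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .capacity import capacity_breakpoints, capacity_model_at
from .core import DelayedRateSet, RateSet, delayed_model_at, simple_model_at
from .fitting import FitObservations, fit_capacity_model
from .mortality import DeathRateSet, mortality_model_at
from .oracle import capacity_ode, delayed_ode, integrate, mortality_ode, ptc_ode, simple_ode
from .ptc import PTCRateSet, ptc_model_at

__all__ = [
    "Scenario",
    "ScenarioError",
    "VARIANTS",
    "load_scenario",
    "dump_scenario",
    "scenario_hash",
    "bundled_scenario_path",
    "resolve_rates",
    "build_trajectory",
    "write_trajectory_csv",
]

VARIANTS = ("simple", "delayed", "capacity", "ptc", "ptc_mortality")

_RATE_KEYS = {
    "simple": ("ka_per_day", "kd_per_day"),
    "delayed": ("ks_per_day", "ka_per_day", "kd_per_day"),
    "capacity": ("ka_per_day", "kd_per_day", "k_prime_per_day"),
    "ptc": ("kpaa_per_day", "kpda_per_day", "kpap_per_day", "kpdp_per_day",
            "ka_prime_per_day", "kp_prime_per_day"),
}
_RATE_KEYS["ptc_mortality"] = _RATE_KEYS["ptc"]
_DEATH_KEYS = ("omega_s_per_day", "omega_a_per_day", "omega_p_per_day", "omega_d_per_day")
_FIT_KEYS = ("t1_days", "t99_days", "tau_days")
_FITTABLE = ("capacity", "ptc", "ptc_mortality")


class ScenarioError(ValueError):
    """Scenario validation failure; ``problems`` lists every issue found."""

    def __init__(self, problems: list[str]):
        super().__init__("invalid scenario: " + "; ".join(problems))
        self.problems = problems


@dataclass
class Scenario:
    """A validated model scenario."""

    variant: str
    rates: dict[str, float] = field(default_factory=dict)
    fit: dict[str, float] | None = None
    deaths: dict[str, float] | None = None
    n0_persons: float = 1.0
    a0_persons: float | None = None
    p0_persons: float | None = None
    threshold: float = 0.99
    t_max_days: float | None = None
    dt_days: float = 0.02

    def __post_init__(self) -> None:
        problems = []
        if self.variant not in VARIANTS:
            problems.append(f"variant must be one of {VARIANTS}, got {self.variant!r}")
            raise ScenarioError(problems)
        needed = _RATE_KEYS[self.variant]
        fit_ok = self.variant in _FITTABLE and self.fit is not None
        if fit_ok:
            missing_fit = [k for k in _FIT_KEYS if k not in self.fit]
            if missing_fit:
                problems.append(f"fit block missing keys: {missing_fit}")
        else:
            missing = [k for k in needed if k not in self.rates]
            if missing:
                problems.append(
                    f"missing rate keys for variant {self.variant!r}: {missing}"
                    + (" (or provide a fit block)" if self.variant in _FITTABLE else "")
                )
        extra = [k for k in self.rates if k not in needed]
        if extra:
            warnings.warn(f"unused rate keys for variant {self.variant!r}: {extra}", stacklevel=2)
        for key, val in self.rates.items():
            if key in needed and val < 0:
                problems.append(f"rate {key} must be nonnegative, got {val}")
        if self.variant == "ptc_mortality":
            if self.deaths is None:
                problems.append("variant 'ptc_mortality' requires a deaths block")
            else:
                missing_d = [k for k in _DEATH_KEYS if k not in self.deaths]
                if missing_d:
                    problems.append(f"deaths block missing keys: {missing_d}")
        if not self.n0_persons > 0:
            problems.append(f"n0_persons must be positive, got {self.n0_persons}")
        if self.a0_persons is not None and self.p0_persons is not None:
            if abs(self.a0_persons + self.p0_persons - self.n0_persons) > 1e-9 * self.n0_persons:
                problems.append(
                    f"a0_persons + p0_persons must equal n0_persons "
                    f"({self.a0_persons} + {self.p0_persons} != {self.n0_persons})"
                )
        if not 0.0 < self.threshold < 1.0:
            problems.append(f"threshold must lie in (0, 1), got {self.threshold}")
        if problems:
            raise ScenarioError(problems)


def _to_dict(scenario: Scenario) -> dict:
    out: dict = {"variant": scenario.variant, "n0_persons": scenario.n0_persons,
                 "threshold": scenario.threshold, "dt_days": scenario.dt_days}
    if scenario.rates:
        out["rates"] = dict(scenario.rates)
    if scenario.fit is not None:
        out["fit"] = dict(scenario.fit)
    if scenario.deaths is not None:
        out["deaths"] = dict(scenario.deaths)
    if scenario.a0_persons is not None:
        out["a0_persons"] = scenario.a0_persons
    if scenario.p0_persons is not None:
        out["p0_persons"] = scenario.p0_persons
    if scenario.t_max_days is not None:
        out["t_max_days"] = scenario.t_max_days
    return out


def load_scenario(path: str | Path) -> Scenario:
    """Load and validate a scenario YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or not raw:
        raise ScenarioError([
            "scenario file is empty or not a mapping; required keys: "
            "variant (+ rates or fit block, deaths block for ptc_mortality)"
        ])
    known = {"variant", "rates", "fit", "deaths", "n0_persons", "a0_persons",
             "p0_persons", "threshold", "t_max_days", "dt_days"}
    unknown = sorted(set(raw) - known)
    if unknown:
        warnings.warn(f"ignoring unknown scenario keys: {unknown}", stacklevel=2)
    kwargs = {k: raw[k] for k in known if k in raw}
    if "variant" not in kwargs:
        raise ScenarioError(["missing required key 'variant'"])
    return Scenario(**kwargs)


def dump_scenario(scenario: Scenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(scenario), sort_keys=True))


def scenario_hash(scenario: Scenario) -> str:
    """Stable sha256 of the canonical scenario content (provenance tag)."""
    blob = json.dumps(_to_dict(scenario), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def bundled_scenario_path(name: str = "haiti") -> Path:
    """Path of a scenario bundled with the package (e.g. ``haiti``)."""
    return Path(str(resources.files("surgekinetics").joinpath(f"data/{name}.yaml")))


def resolve_rates(scenario: Scenario):
    """Materialize the scenario's rate objects.

    Returns (RateSet | DelayedRateSet | PTCRateSet, DeathRateSet | None).
    For fittable variants with a ``fit`` block the single-center rates are
    fitted first; the PTC-side rates then default to the adult values
    unless given explicitly.
    """
    r = scenario.rates
    if scenario.variant == "simple":
        return RateSet(ka=r["ka_per_day"], kd=r["kd_per_day"]), None
    if scenario.variant == "delayed":
        return DelayedRateSet(ks=r["ks_per_day"], ka=r["ka_per_day"], kd=r["kd_per_day"]), None

    if scenario.fit is not None:
        obs = FitObservations(t1_obs=scenario.fit["t1_days"],
                              t99_obs=scenario.fit["t99_days"],
                              tau=scenario.fit["tau_days"])
        adult = fit_capacity_model(obs, compute_sigmas=False).rates
    else:
        adult = None

    deaths = None
    if scenario.deaths is not None:
        d = scenario.deaths
        deaths = DeathRateSet(
            omega_s=d["omega_s_per_day"], omega_a=d["omega_a_per_day"],
            omega_p=d["omega_p_per_day"], omega_d=d["omega_d_per_day"],
            omega_a_prime=d.get("omega_a_prime_per_day", math.nan),
            omega_p_prime=d.get("omega_p_prime_per_day", math.nan),
        )

    if scenario.variant == "capacity":
        rates = adult if adult is not None else RateSet(
            ka=r["ka_per_day"], kd=r["kd_per_day"], k_prime=r["k_prime_per_day"])
        return rates, deaths

    if r:
        rates = PTCRateSet(
            kpaa=r["kpaa_per_day"], kpda=r["kpda_per_day"],
            kpap=r["kpap_per_day"], kpdp=r["kpdp_per_day"],
            ka_prime=r["ka_prime_per_day"], kp_prime=r["kp_prime_per_day"])
    else:
        rates = PTCRateSet(kpaa=adult.ka, kpda=adult.kd, kpap=adult.ka,
                           kpdp=adult.kd, ka_prime=adult.k_prime, kp_prime=adult.k_prime)
    return rates, deaths


def build_trajectory(scenario: Scenario, t_max: float | None = None,
                     dt: float | None = None, oracle: bool = False) -> pd.DataFrame:
    """Evaluate the scenario's model on a regular time grid.

    Columns: ``t_days``, one population-fraction column per compartment,
    and ``region``.  With ``oracle=True`` the closed forms are replaced by
    the fixed-step RK integration of the governing ODEs (region labels
    from the closed-form breakpoints).
    """
    rates, deaths = resolve_rates(scenario)
    t_max = t_max if t_max is not None else (scenario.t_max_days or _default_horizon(scenario, rates))
    dt = dt if dt is not None else scenario.dt_days
    t = np.arange(0.0, t_max + 0.5 * dt, dt)

    if scenario.variant == "simple":
        cols, states, regions = ("Ns", "Na", "Nd"), simple_ode(rates), None
        closed = lambda ti: (tuple(simple_model_at(ti, rates)), "I")  # noqa: E731
    elif scenario.variant == "delayed":
        cols, states = ("Ne", "Ns", "Na", "Nd"), delayed_ode(rates)
        closed = lambda ti: (tuple(delayed_model_at(ti, rates)), "I")  # noqa: E731
    elif scenario.variant == "capacity":
        cols, states = ("Ns", "Na", "Nd"), capacity_ode(rates)
        closed = lambda ti: _split(capacity_model_at(ti, rates))  # noqa: E731
    elif scenario.variant == "ptc":
        cols, states = ("Ps", "Paa", "Pap", "Pd"), ptc_ode(rates)
        closed = lambda ti: _split(ptc_model_at(ti, rates))  # noqa: E731
    else:
        cols, states = ("Ps", "Paa", "Pap", "Pd", "PD"), mortality_ode(rates, deaths)
        closed = lambda ti: _split(mortality_model_at(ti, rates, deaths))  # noqa: E731

    region_col = [closed(float(ti))[1] for ti in t]
    if oracle:
        values = integrate(states, t, step=min(dt / 10.0, 1e-3))
    else:
        values = np.array([closed(float(ti))[0] for ti in t])
    df = pd.DataFrame(values * scenario.n0_persons, columns=[f"{c}_persons" for c in cols])
    df.insert(0, "t_days", t)
    df["region"] = region_col
    return df


def _split(result):
    state, region = result
    return tuple(state), region


def _default_horizon(scenario: Scenario, rates) -> float:
    if scenario.variant == "simple":
        return 5.0 / min(rates.ka, rates.kd)
    if scenario.variant == "delayed":
        return 5.0 / min(rates.ks, rates.ka, rates.kd)
    if scenario.variant == "capacity":
        return capacity_breakpoints(rates).t2 + 5.0 / rates.kd
    return 14.0


def write_trajectory_csv(df: pd.DataFrame, path: str | Path, scenario: Scenario | None = None) -> None:
    """Write a trajectory CSV with a provenance comment line carrying the
    scenario hash."""
    path = Path(path)
    with path.open("w") as fh:
        if scenario is not None:
            fh.write(f"# scenario_sha256={scenario_hash(scenario)} variant={scenario.variant}\n")
        df.to_csv(fh, index=False)
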