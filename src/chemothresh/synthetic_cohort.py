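"""Registry-style synthetic cohort generator with known ground truth.

The real study population — a linked registry of early-stage ER+/HER2-
breast-cancer patients with Oncotype DX recurrence scores (RS) — is
access-restricted, so this module simulates a cohort with the same
statistical structure and a *known* chemotherapy-benefit threshold, giving
every downstream stage a recoverable ground truth:

* race drawn from a configurable mix; RS drawn per race from a truncated
  normal on [0, 100] and rounded to an integer (registries report integer
  scores); the default means place the black distribution ~2 RS units above
  the white and Asian ones;
* chemotherapy assigned by a logistic propensity in RS, so higher-score
  patients are more often treated — confounding by indication, the bias the
  counterfactual analysis must undo;
* breast-cancer-specific death times exponential with proportional-hazards
  rate lambda0 * exp(beta_rs*RS + beta_age*(age-60)/10 + chemo*gamma(RS)),
  where the treatment log-hazard ratio gamma(RS) = -s*(RS - theta_race)
  changes sign at the true benefit threshold theta: chemotherapy is harmful
  below theta and protective above it;
* independent exponential dropout and administrative censoring at a fixed
  horizon; observed times are rounded to whole months (minimum 1), as
  registries report follow-up.

Columns are generated in a fixed, documented order from a single seeded
stream (race, rs, age, chemo, event time, dropout time), so equal (config,
seed) pairs produce bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import COLUMNS


class ConfigurationError(ValueError):
    """A generator parameter is outside its valid range; names the field."""


def _as_race_dict(value, name: str) -> dict:
    if not isinstance(value, dict):
        raise ConfigurationError(f"{name} must be a mapping keyed by race")
    return dict(value)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic registry cohort.

    Time is measured in months.  ``theta_per_race`` holds the true benefit
    threshold in RS units; ``benefit_slope`` is the treatment-effect slope s
    in log-hazard-ratio per RS unit, so gamma(RS) = -s*(RS - theta).
    ``propensity_a``/``propensity_b`` parameterise
    P(chemo | RS) = logistic(a + b*RS).
    """

    n_patients: int = 20000
    race_mix: dict = field(default_factory=lambda: {"white": 0.843, "black": 0.083, "asian": 0.074})
    rs_dist_per_race: dict = field(default_factory=lambda: {
        "white": (17.0, 8.0), "black": (19.0, 8.0), "asian": (17.0, 8.0)})
    age_range: tuple = (35.0, 80.0)
    baseline_hazard: float = 0.002       # events per month at RS=0, age 60, no chemo
    beta_rs: float = 0.03                # log-hazard per RS unit
    beta_age: float = 0.2                # log-hazard per decade of age (centred at 60)
    theta_per_race: dict = field(default_factory=lambda: {"white": 25.0, "black": 25.0, "asian": 25.0})
    benefit_slope: float = 0.02          # s; log-HR per RS unit of distance from theta
    propensity_a: float = -2.0
    propensity_b: float = 0.08
    censor_time_max: float = 120.0       # administrative censoring horizon, months
    dropout_rate: float = 0.003          # per-month dropout hazard
    ln_status: str = "negative"          # eligibility field stamped on every row
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be at least 1")
        mix = _as_race_dict(self.race_mix, "race_mix")
        if any(p < 0 for p in mix.values()):
            raise ConfigurationError("race_mix proportions must be non-negative")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("race_mix must sum to 1 within 1e-9")
        for race in mix:
            if race not in self.rs_dist_per_race:
                raise ConfigurationError(f"rs_dist_per_race missing entry for race {race!r}")
            if race not in self.theta_per_race:
                raise ConfigurationError(f"theta_per_race missing entry for race {race!r}")
        for race, (mu, sd) in _as_race_dict(self.rs_dist_per_race, "rs_dist_per_race").items():
            if sd <= 0:
                raise ConfigurationError(f"rs_dist_per_race sd must be positive for race {race!r}")
        for race, theta in _as_race_dict(self.theta_per_race, "theta_per_race").items():
            if not 0 <= theta <= 100:
                raise ConfigurationError(f"theta_per_race must lie in [0, 100] for race {race!r}")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigurationError("age_range must be increasing")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if self.benefit_slope < 0:
            raise ConfigurationError("benefit_slope must be non-negative")
        if self.censor_time_max <= 0:
            raise ConfigurationError("censor_time_max must be positive")
        if self.dropout_rate < 0:
            raise ConfigurationError("dropout_rate must be non-negative")
        if self.ln_status not in ("negative", "positive"):
            raise ConfigurationError("ln_status must be 'negative' or 'positive'")


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters emitted alongside every cohort, for recovery tests."""

    theta_per_race: dict
    hazard_model_params: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(theta_per_race=d["theta_per_race"],
                   hazard_model_params=d["hazard_model_params"])


def _log_hazard(config: SyntheticConfig, rs, age, chemo, race_theta):
    """Linear predictor eta of the generator's proportional-hazards model."""
    gamma = -config.benefit_slope * (np.asarray(rs, dtype=float) - race_theta)
    return (config.beta_rs * np.asarray(rs, dtype=float)
            + config.beta_age * (np.asarray(age, dtype=float) - 60.0) / 10.0
            + np.asarray(chemo, dtype=float) * gamma)


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a cohort of ``config.n_patients`` rows plus its ground truth.

    All eligibility fields are stamped with eligible values (stage I, ER+,
    PR+, luminal A, configured lymph-node status) so the default analysis
    criteria retain every row.  Observed time is min(event, dropout,
    administrative censor), rounded to whole months with a floor of 1;
    the event indicator is ``bcss_death`` when the death time came first.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    races = sorted(config.race_mix)
    probs = np.array([config.race_mix[r] for r in races])

    # Fixed generation order: race, rs, age, chemo, event time, dropout time.
    race = rng.choice(races, size=n, p=probs)
    rs = np.empty(n, dtype=float)
    for r in races:
        mask = race == r
        mu, sd = config.rs_dist_per_race[r]
        a, b = (0.0 - mu) / sd, (100.0 - mu) / sd
        rs[mask] = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=mask.sum(), random_state=rng)
    rs = np.clip(np.round(rs), 0, 100).astype(int)
    age = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    p_chemo = 1.0 / (1.0 + np.exp(-(config.propensity_a + config.propensity_b * rs)))
    chemo = rng.random(n) < p_chemo

    theta = np.array([config.theta_per_race[r] for r in race])
    hazard = config.baseline_hazard * np.exp(_log_hazard(config, rs, age, chemo, theta))
    event_time = rng.exponential(1.0 / hazard)
    if config.dropout_rate > 0:
        dropout_time = rng.exponential(1.0 / config.dropout_rate, size=n)
    else:
        dropout_time = np.full(n, np.inf)

    censor_time = np.minimum(dropout_time, config.censor_time_max)
    observed = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    time_months = np.maximum(1.0, np.round(observed))  # registry-style whole months

    cohort = pd.DataFrame({
        "id": [f"P{i:07d}" for i in range(n)],
        "age": age,
        "race": race,
        "stage": "I",
        "grade": "moderate",
        "er_status": "positive",
        "pr_status": "positive",
        "subtype": "luminalA",
        "ln_status": config.ln_status,
        "rs": rs.astype(float),
        "chemo": np.where(chemo, "yes", "no_unknown"),
        "time_months": time_months,
        "event": np.where(event, "bcss_death", "censored"),
    })[COLUMNS]
    cohort.attrs["generator_config"] = dataclasses.asdict(config)

    truth = GroundTruth(
        theta_per_race=dict(config.theta_per_race),
        hazard_model_params={
            "baseline_hazard": config.baseline_hazard,
            "beta_rs": config.beta_rs,
            "beta_age": config.beta_age,
            "benefit_slope": config.benefit_slope,
            "propensity_a": config.propensity_a,
            "propensity_b": config.propensity_b,
            "censor_time_max": config.censor_time_max,
            "dropout_rate": config.dropout_rate,
        },
    )
    return cohort, truth


def true_relative_risk(config: SyntheticConfig, rs: float, race: str,
                       age: float = 60.0, horizon: float = 120.0) -> float:
    """Closed-form counterfactual risk difference F_yes(h) - F_no(h).

    F(t) = 1 - exp(-lambda0 * exp(eta) * t) under the generator's hazard with
    the chemotherapy indicator forced to yes or no.  Positive below the
    race's true threshold theta (treatment harmful), zero at theta, negative
    above it (treatment beneficial), at every horizon, whenever s > 0.
    """
    if not 0 <= rs <= 100:
        raise ValueError("rs must lie in [0, 100]")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    theta = config.theta_per_race[race]
    eta_no = _log_hazard(config, rs, age, 0.0, theta)
    eta_yes = _log_hazard(config, rs, age, 1.0, theta)
    f_no = 1.0 - np.exp(-config.baseline_hazard * np.exp(eta_no) * horizon)
    f_yes = 1.0 - np.exp(-config.baseline_hazard * np.exp(eta_yes) * horizon)
    return float(f_yes - f_no)
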