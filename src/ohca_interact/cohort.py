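"""Synthetic Utstein-style out-of-hospital cardiac arrest (OHCA) cohorts.

The real prehospital registry behind this kind of analysis is not public, so
this module generates cohorts with the same tabular structure (24 data items
per case: demographics, witness status, bystander actions, EMS crew, initial
rhythm, interventions with counts and contact-to-intervention times, response
and transport times, ROSC, and the one-month CPC 1/2 outcome) from an
explicit generative model.  The outcome is drawn from a logistic model whose
coefficients — including transport x intervention-delay interaction terms —
are known ground truth, which makes every downstream stage (encoding,
training, counterfactual sweeps) verifiable by parameter recovery.

Marginal distributions default to a published rural-Japan registry profile:
~4% favorable (CPC 1/2) outcomes, ~12% defibrillated, ~36% receiving
adrenaline, right-skewed times (log-normal, e.g. contact-to-hospital median
28 min, IQR 22-36).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EffectModel",
    "CohortConfig",
    "CohortError",
    "generate_cohort",
    "true_outcome_probability",
    "linear_predictor",
    "write_cohort_csv",
    "read_cohort_csv",
    "load_config",
    "CATEGORICAL_LEVELS",
    "COLUMNS",
]

SHOCKABLE_RHYTHMS = ("VF", "pulseless_VT")
EMS_WITNESS_TYPES = ("firefighter", "paramedic", "emergency_lifesaver")

#: canonical column order of the cohort CSV dialect
COLUMNS = [
    "age_years",
    "sex",
    "guideline_era",
    "witnessed",
    "witness_type",
    "bystander_cpr",
    "bystander_cpr_actions",
    "bystander_aed",
    "ems_lifesaver",
    "ems_doctor",
    "first_rhythm",
    "defib_performed",
    "defib_count",
    "defib_time_min",
    "adrenaline_given",
    "adrenaline_count",
    "adrenaline_time_min",
    "advanced_airway",
    "medication_route",
    "call_to_contact_min",
    "contact_to_arrival_min",
    "prehospital_rosc",
    "cause_cardiogenic",
    "outcome_cpc12",
]

#: level lists for the categorical items (missing is encoded as an empty field)
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "guideline_era": ("g2010", "g2015"),
    "witnessed": ("yes", "no"),
    "witness_type": (
        "none",
        "family",
        "friends",
        "colleagues",
        "passersby",
        "other",
        "firefighter",
        "paramedic",
        "emergency_lifesaver",
    ),
    "bystander_cpr": ("yes", "no"),
    "bystander_cpr_actions": ("none", "compressions_only", "compressions_and_ventilations"),
    "bystander_aed": ("yes", "no"),
    "ems_lifesaver": ("yes", "no"),
    "ems_doctor": ("yes", "no"),
    "first_rhythm": ("VF", "pulseless_VT", "PEA", "asystole", "other"),
    "medication_route": ("yes", "no"),
    "advanced_airway": ("yes", "no"),
    "prehospital_rosc": ("yes", "no"),
}


class CohortError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass(frozen=True)
class EffectModel:
    """Ground-truth logistic outcome model.

    The linear predictor is

        eta = intercept
            + b_age * age + b_transport * transport
            + b_defib_delay * defib_delay + b_drug_delay * drug_delay
            + b_shockable * shockable + b_witnessed * witnessed
            + b_bystander_cpr * cpr
            + g_transport_defib * (transport - c_t) * (defib_delay - c_defib)
            + g_transport_drug * (transport - c_t) * (drug_delay - c_drug)

    with times in minutes, age in years, indicators in {0, 1}.  Delay terms
    contribute only for records in which the intervention was performed.
    The interaction coefficients (log-odds per minute^2) are what the
    two-factor counterfactual sweep is designed to recover.
    """

    intercept: float = 0.0
    age: float = -0.08
    transport: float = -0.06
    defib_delay: float = -0.20
    drug_delay: float = -0.10
    shockable: float = 4.0
    witnessed: float = 1.6
    bystander_cpr: float = 1.0
    transport_x_defib: float = -0.008
    transport_x_drug: float = -0.004
    # centering constants for the interaction terms (marginal time medians)
    transport_center: float = 28.0
    defib_delay_center: float = 4.0
    drug_delay_center: float = 16.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not math.isfinite(value):
                raise CohortError(f"EffectModel.{name} must be finite, got {value!r}")

    def coefficients(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if k != "intercept"}


def _lognorm_from_quartiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) moment-fitted to a median and IQR."""
    if median <= 0 or q1 <= 0 or q3 <= q1:
        raise CohortError(f"invalid quartiles ({median}, [{q1}, {q3}]) for a time variable")
    z75 = 0.6744897501960817
    return math.log(median), math.log(q3 / q1) / (2.0 * z75)


# registry-profile time quartiles (minutes): median, Q1, Q3
_DEFAULT_TIME_QUARTILES = {
    "call_to_contact_min": (8.0, 7.0, 10.0),
    "contact_to_arrival_min": (28.0, 22.0, 36.0),
    "defib_time_min": (4.0, 3.0, 12.0),
    "adrenaline_time_min": (16.0, 12.0, 21.0),
}


def default_time_distributions() -> dict[str, tuple[float, float]]:
    return {k: _lognorm_from_quartiles(*v) for k, v in _DEFAULT_TIME_QUARTILES.items()}


def default_rhythm_mix() -> dict[str, float]:
    # VF 9%, pulseless VT ~1%, PEA 20%, asystole 65%, other ~5%
    return {
        "VF": 0.085,
        "pulseless_VT": 0.006,
        "PEA": 0.202,
        "asystole": 0.655,
        "other": 0.052,
    }


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic cohort generator.

    Defaults reproduce the registry profile: 11,504 recorded cases of which
    ~72% survive the adult/cardiogenic inclusion filter, ~4% CPC 1/2
    prevalence among included cases, 12% defibrillated, 36% given adrenaline.
    """

    n_records: int = 11504
    prevalence_target: float = 0.04
    rhythm_mix: Mapping[str, float] = field(default_factory=default_rhythm_mix)
    defib_fraction: float = 0.12
    adrenaline_fraction: float = 0.36
    time_distributions: Mapping[str, tuple[float, float]] = field(
        default_factory=default_time_distributions
    )
    missingness: Mapping[str, float] = field(default_factory=dict)
    default_missingness: float = 0.02
    effects: EffectModel = field(default_factory=EffectModel)
    exclusion_under18: float = 0.02
    exclusion_noncardiogenic: float = 0.265
    calibrate_intercept: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise CohortError(f"n_records must be >= 0, got {self.n_records}")
        if not 0.0 < self.prevalence_target < 1.0:
            raise CohortError(f"prevalence_target must lie in (0,1), got {self.prevalence_target}")
        mix = dict(self.rhythm_mix)
        if set(mix) != set(CATEGORICAL_LEVELS["first_rhythm"]):
            raise CohortError(f"rhythm_mix must cover levels {CATEGORICAL_LEVELS['first_rhythm']}")
        total = sum(mix.values())
        if any(p < 0 for p in mix.values()) or abs(total - 1.0) > 1e-9:
            raise CohortError(f"rhythm_mix probabilities must be >= 0 and sum to 1, got {total}")
        for name in ("defib_fraction", "adrenaline_fraction", "exclusion_under18",
                     "exclusion_noncardiogenic", "default_missingness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortError(f"{name} must lie in [0,1], got {v}")
        for fld, p in dict(self.missingness).items():
            if fld not in CATEGORICAL_LEVELS:
                raise CohortError(f"missingness refers to unknown categorical field {fld!r}")
            if not 0.0 <= p <= 1.0:
                raise CohortError(f"missingness[{fld!r}] must lie in [0,1], got {p}")
        for fld, (mu, sigma) in dict(self.time_distributions).items():
            if fld not in _DEFAULT_TIME_QUARTILES:
                raise CohortError(f"time_distributions refers to unknown time field {fld!r}")
            if not (math.isfinite(mu) and math.isfinite(sigma) and sigma >= 0):
                raise CohortError(f"time_distributions[{fld!r}] must be finite with sigma >= 0")

    def missing_prob(self, fld: str) -> float:
        return float(dict(self.missingness).get(fld, self.default_missingness))


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def linear_predictor(df: pd.DataFrame, effects: EffectModel) -> np.ndarray:
    """Ground-truth linear predictor (log-odds), vectorized over a cohort frame.

    Uses the *true* covariate values (pre-missingness columns are fine since
    missingness only blanks the recorded categorical fields, not the latent
    state used here: witnessed/rhythm/CPR indicator columns must be present).
    """
    age = df["age_years"].to_numpy(dtype=float)
    transport = df["contact_to_arrival_min"].to_numpy(dtype=float)
    shockable = df["first_rhythm"].isin(SHOCKABLE_RHYTHMS).to_numpy(dtype=float)
    witnessed = (df["witnessed"] == "yes").to_numpy(dtype=float)
    cpr = (df["bystander_cpr"] == "yes").to_numpy(dtype=float)
    defib_done = df["defib_performed"].to_numpy(dtype=float) != 0
    drug_done = df["adrenaline_given"].to_numpy(dtype=float) != 0
    defib_delay = np.where(defib_done, np.nan_to_num(df["defib_time_min"].to_numpy(dtype=float)), 0.0)
    drug_delay = np.where(drug_done, np.nan_to_num(df["adrenaline_time_min"].to_numpy(dtype=float)), 0.0)
    e = effects
    # interaction terms are centered at the marginal time medians so that a
    # nonzero coefficient modifies effects without dominating the base rates;
    # they contribute only where the intervention was performed
    t_c = transport - e.transport_center
    return (
        e.intercept
        + e.age * age
        + e.transport * transport
        + e.defib_delay * defib_delay
        + e.drug_delay * drug_delay
        + e.shockable * shockable
        + e.witnessed * witnessed
        + e.bystander_cpr * cpr
        + e.transport_x_defib * t_c * np.where(defib_done, defib_delay - e.defib_delay_center, 0.0)
        + e.transport_x_drug * t_c * np.where(drug_done, drug_delay - e.drug_delay_center, 0.0)
    )


def true_outcome_probability(record: Mapping | pd.Series | pd.DataFrame,
                             effects: EffectModel) -> float | np.ndarray:
    """P(CPC 1/2) under the generative model for one record or a frame."""
    if isinstance(record, pd.DataFrame):
        return _sigmoid(linear_predictor(record, effects))
    df = pd.DataFrame([dict(record)])
    return float(_sigmoid(linear_predictor(df, effects))[0])


def _draw_covariates(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_records
    df = pd.DataFrame(index=range(n))

    # inclusion-filter attributes: under-18 and non-cardiogenic drawn independently
    under18 = rng.random(n) < cfg.exclusion_under18
    df["cause_cardiogenic"] = (rng.random(n) >= cfg.exclusion_noncardiogenic).astype(int)
    adult_age = np.clip(np.round(rng.normal(78.0, 13.0, n)), 18, 105)
    child_age = rng.integers(1, 18, n)
    df["age_years"] = np.where(under18, child_age, adult_age).astype(int)

    df["sex"] = np.where(rng.random(n) < 0.56, "male", "female")
    df["guideline_era"] = np.where(rng.random(n) < 0.53, "g2010", "g2015")

    witnessed = rng.random(n) < 0.40
    df["witnessed"] = np.where(witnessed, "yes", "no")
    # conditional witness mix (family dominates; EMS-witnessed ~8% of total)
    witness_levels = np.array(
        ["family", "friends", "colleagues", "passersby", "other",
         "firefighter", "paramedic", "emergency_lifesaver"]
    )
    witness_p = np.array([0.513, 0.028, 0.021, 0.020, 0.213, 0.001, 0.052, 0.152])
    witness_p = witness_p / witness_p.sum()
    wt = witness_levels[rng.choice(len(witness_levels), size=n, p=witness_p)]
    df["witness_type"] = np.where(witnessed, wt, "none")

    cpr = rng.random(n) < 0.52
    df["bystander_cpr"] = np.where(cpr, "yes", "no")
    actions = np.where(
        rng.random(n) < 0.89, "compressions_only", "compressions_and_ventilations"
    )
    df["bystander_cpr_actions"] = np.where(cpr, actions, "none")
    df["bystander_aed"] = np.where(rng.random(n) < 0.02, "yes", "no")
    df["ems_lifesaver"] = np.where(rng.random(n) < 0.98, "yes", "no")
    df["ems_doctor"] = np.where(rng.random(n) < 0.06, "yes", "no")

    rhythms = list(CATEGORICAL_LEVELS["first_rhythm"])
    mix = dict(cfg.rhythm_mix)
    p = np.array([mix[r] for r in rhythms])
    df["first_rhythm"] = np.array(rhythms)[rng.choice(len(rhythms), size=n, p=p / p.sum())]
    shockable = df["first_rhythm"].isin(SHOCKABLE_RHYTHMS).to_numpy()

    # defibrillation: nearly always for shockable initial rhythms, occasionally
    # otherwise (rhythms that became shockable later); solved so the overall
    # fraction matches cfg.defib_fraction
    p_shock = float(sum(mix[r] for r in SHOCKABLE_RHYTHMS))
    p_given_shockable = min(0.95, cfg.defib_fraction / max(p_shock, 1e-9))
    rest = max(1.0 - p_shock, 1e-9)
    p_given_other = float(np.clip((cfg.defib_fraction - p_given_shockable * p_shock) / rest, 0.0, 1.0))
    defib = np.where(shockable, rng.random(n) < p_given_shockable, rng.random(n) < p_given_other)
    df["defib_performed"] = defib.astype(int)

    drug = rng.random(n) < cfg.adrenaline_fraction
    df["adrenaline_given"] = drug.astype(int)
    df["advanced_airway"] = np.where(rng.random(n) < 0.89, "yes", "no")
    df["medication_route"] = np.where(rng.random(n) < 0.46, "yes", "no")

    tdist = dict(cfg.time_distributions)

    def draw_minutes(fld: str, size: int) -> np.ndarray:
        mu, sigma = tdist[fld]
        return np.maximum(np.round(rng.lognormal(mu, sigma, size)), 0.0)

    df["call_to_contact_min"] = draw_minutes("call_to_contact_min", n)
    df["contact_to_arrival_min"] = draw_minutes("contact_to_arrival_min", n)
    df["defib_time_min"] = np.where(defib, draw_minutes("defib_time_min", n), np.nan)
    df["defib_count"] = np.where(defib, 1 + rng.poisson(1.0, n), 0).astype(int)
    df["adrenaline_time_min"] = np.where(drug, draw_minutes("adrenaline_time_min", n), np.nan)
    df["adrenaline_count"] = np.where(drug, 1 + rng.poisson(0.8, n), 0).astype(int)
    return df


def _calibrate_intercept(df: pd.DataFrame, effects: EffectModel, target: float) -> float:
    """Bisection on the intercept so the included subgroup hits the target prevalence."""
    included = df[(df["age_years"] >= 18) & (df["cause_cardiogenic"] == 1)]
    if len(included) == 0:
        included = df
    eta0 = linear_predictor(included, replace(effects, intercept=0.0))

    def mean_prob(c: float) -> float:
        return float(np.mean(_sigmoid(eta0 + c)))

    lo, hi = -40.0, 15.0
    if mean_prob(lo) > target or mean_prob(hi) < target:
        raise CohortError("intercept calibration failed: target prevalence out of reach")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_prob(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _apply_missingness(df: pd.DataFrame, cfg: CohortConfig, rng: np.random.Generator) -> None:
    """MCAR blanking of recorded categorical fields (empty string = missing)."""
    for fld in CATEGORICAL_LEVELS:
        p = cfg.missing_prob(fld)
        if p > 0:
            mask = rng.random(len(df)) < p
            df.loc[mask, fld] = ""


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a pre-filter cohort of exactly ``config.n_records`` records.

    Deterministic given (config, seed).  ROSC and the CPC 1/2 outcome are
    drawn from the ground-truth logistic model; if ``calibrate_intercept`` the
    intercept is first bisected so the included (adult, cardiogenic) subgroup
    prevalence matches ``prevalence_target``.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))
    df = _draw_covariates(config, rng)
    if len(df) == 0:
        for col in COLUMNS:
            if col not in df.columns:
                df[col] = pd.Series(dtype=float)
        return df[COLUMNS]

    effects = config.effects
    if config.calibrate_intercept:
        effects = replace(effects, intercept=_calibrate_intercept(df, effects, config.prevalence_target))
    prob = _sigmoid(linear_predictor(df, effects))
    df["outcome_cpc12"] = (rng.random(len(df)) < prob).astype(int)
    # prehospital ROSC correlates with a favorable outcome
    rosc_p = np.where(df["outcome_cpc12"] == 1, 0.60, 0.08)
    df["prehospital_rosc"] = np.where(rng.random(len(df)) < rosc_p, "yes", "no")

    _apply_missingness(df, config, rng)
    return df[COLUMNS].copy()


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write the canonical CSV dialect (missing categoricals as empty fields)."""
    out = df.copy()
    for col in ("defib_time_min", "adrenaline_time_min", "call_to_contact_min",
                "contact_to_arrival_min"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:g}")
    out.to_csv(path, index=False, lineterminator="\n")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: str for c in CATEGORICAL_LEVELS}, keep_default_na=False)
    for col in CATEGORICAL_LEVELS:
        if col in df.columns:
            df[col] = df[col].fillna("")
    for col in ("defib_time_min", "adrenaline_time_min", "call_to_contact_min",
                "contact_to_arrival_min"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col].replace("", np.nan))
    for col in ("age_years", "defib_count", "adrenaline_count", "defib_performed",
                "adrenaline_given", "cause_cardiogenic", "outcome_cpc12"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col]).astype(int)
    return df


def load_config(path) -> CohortConfig:
    """Read a CohortConfig from YAML or JSON."""
    text = open(path).read()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if "effects" in data:
        data["effects"] = EffectModel(**data["effects"])
    if "time_distributions" in data:
        data["time_distributions"] = {
            k: tuple(v) for k, v in data["time_distributions"].items()
        }
    return CohortConfig(**data)
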