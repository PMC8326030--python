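"""Life-table health impact assessment for dietary change.

An IOMLIFET-style multi-cohort life table converts the dietary deltas of an
optimized pathway into years of life gained and the change in life
expectancy at birth, separately by sex.

Model outline
-------------
* Exposure deltas (g/person/day) are computed for fruit, non-legume
  vegetables, legumes, red meat and processed meat (poultry changes carry no
  relative risk and are excluded).
* Each exposure-outcome pair has a log-linear exposure-response:
  ``RR(delta) = exp(beta * delta)`` with ``beta = +/- ln(RR_unit) / unit_g``
  (sign by the stated direction of the unit change). Several exposures
  acting on one disease multiply.
* Effects phase in with S-shaped (normal-CDF) time lags: cardiometabolic
  outcomes reach full effect after 10 years; cancers are unchanged for the
  first 10 years and reach full effect after 30. The lag applies on the
  log-RR scale, preserving multiplicativity.
* Cause-specific mortality is scaled by the lagged RRs and subtracted from
  all-cause mortality; baseline rates are otherwise held constant, diets are
  adopted instantly at t=0, and the current population is aged forward with
  no in-migration and no new births. Hazards convert to annual death
  probabilities via ``q = 1 - exp(-m)`` with a half-year person-year credit
  for within-year deaths.
* Life expectancy at birth follows a birth cohort entering at t=0 under the
  time-varying impacted rates; the sex-combined change weights males to
  females 105:100 at birth (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm

from .foods import ValidationError, align_diet

__all__ = [
    "OUTCOMES",
    "EXPOSURES",
    "LagProfile",
    "CARDIOMETABOLIC_LAG",
    "CANCER_LAG",
    "OUTCOME_LAG",
    "HealthImpactResult",
    "load_exposure_response",
    "validate_population",
    "read_population_csv",
    "delta_exposures",
    "log_linear_rr",
    "combine_rr",
    "lag_weight",
    "rr_schedule",
    "impacted_mortality",
    "cohort_life_expectancy",
    "population_person_years",
    "health_impact",
    "attribution_fv",
    "sensitivity_bounds",
]

OUTCOMES = (
    "IHD",
    "ischemic_stroke",
    "T2D",
    "colorectal_cancer",
    "lung_cancer",
    "esophageal_cancer",
)
EXPOSURES = ("fruit", "vegetables", "legumes", "red_meat", "processed_meat")

#: Male:female ratio at birth used for the sex-combined life expectancy.
BIRTH_SEX_RATIO = (105.0, 100.0)

DEFAULT_HORIZON = 120


@dataclass(frozen=True)
class LagProfile:
    """Normal-CDF phase-in of a relative risk after a dietary change.

    ``weight(t) = 0`` for ``t < zero_years`` and ``Phi((t - mean) / sd)``
    otherwise; the default sd of ramp/5.164 puts the weight at ~0.005 at the
    start of the ramp and ~0.995 at ``max_years``.
    """

    outcome_class: str
    zero_years: float
    max_years: float
    mean: float
    sd: float


def _profile(outcome_class: str, zero_years: float, max_years: float) -> LagProfile:
    ramp = max_years - zero_years
    return LagProfile(outcome_class, zero_years, max_years, zero_years + ramp / 2, ramp / 5.164)


CARDIOMETABOLIC_LAG = _profile("cardiometabolic", 0.0, 10.0)
CANCER_LAG = _profile("cancer", 10.0, 30.0)

OUTCOME_LAG = {
    "IHD": CARDIOMETABOLIC_LAG,
    "ischemic_stroke": CARDIOMETABOLIC_LAG,
    "T2D": CARDIOMETABOLIC_LAG,
    "colorectal_cancer": CANCER_LAG,
    "lung_cancer": CANCER_LAG,
    "esophageal_cancer": CANCER_LAG,
}


def load_exposure_response() -> pd.DataFrame:
    """The packaged exposure-response table (13 GBD risk-outcome pairs)."""
    with resources.files("fiveaday.data").joinpath("exposure_response.csv").open() as fh:
        er = pd.read_csv(fh)
    bad = ~((er["ci_low"] <= er["rr"]) & (er["rr"] <= er["ci_high"]) & (er["ci_low"] > 0))
    if bad.any():
        raise ValidationError("exposure-response table violates ci_low <= rr <= ci_high > 0")
    return er


def validate_population(pop: pd.DataFrame) -> pd.DataFrame:
    """Validate age/sex population counts and mortality rates."""
    required = ["sex", "age", "population", "all_cause_rate", *OUTCOMES]
    missing = [c for c in required if c not in pop.columns]
    if missing:
        raise ValidationError(f"population table missing columns: {missing}")
    out = pop.copy().reset_index(drop=True)
    if not set(out["sex"]) <= {"male", "female"}:
        raise ValidationError("population sex must be 'male' or 'female'")
    for col in required[1:]:
        vals = pd.to_numeric(out[col], errors="coerce")
        if vals.isna().any() or (vals < 0).any():
            raise ValidationError(f"population column {col!r} must be >= 0")
        out[col] = vals.astype(float)
    cause_sum = out[list(OUTCOMES)].sum(axis=1)
    if (cause_sum > out["all_cause_rate"] + 1e-12).any():
        row = int(out.index[cause_sum > out["all_cause_rate"] + 1e-12][0])
        raise ValidationError(
            f"population row {row + 2}: cause-specific rates exceed the all-cause rate"
        )
    for sex, grp in out.groupby("sex"):
        ages = np.sort(grp["age"].values)
        if not np.array_equal(ages, np.arange(len(ages))):
            raise ValidationError(f"population ages for {sex} must be 0..{len(ages) - 1}")
    return out


def read_population_csv(path) -> pd.DataFrame:
    return validate_population(pd.read_csv(path, comment="#"))


def delta_exposures(baseline, pathway_diet, foods: pd.DataFrame) -> dict[str, float]:
    """Signed intake changes (g/person/day) feeding the risk model.

    Fruit, non-legume vegetables and legumes are tracked separately (legumes
    have their own exposure-response relation); poultry is excluded for lack
    of relative-risk data.
    """
    b = align_diet(baseline, foods).values
    x = align_diet(pathway_diet, foods).values
    cat = foods["category"].values
    delta = x - b
    return {
        "fruit": float(delta[cat == "fruit"].sum()),
        "vegetables": float(delta[cat == "vegetable"].sum()),
        "legumes": float(delta[cat == "legume"].sum()),
        "red_meat": float(delta[cat == "red_meat"].sum()),
        "processed_meat": float(delta[cat == "processed_meat"].sum()),
    }


def log_linear_rr(er_row, delta_g: float, rr_column: str = "rr") -> float:
    """Relative risk for a signed intake change under a log-linear relation.

    ``er_row`` is one exposure-response record with fields ``rr`` (or a CI
    bound named by ``rr_column``), ``unit_g`` and ``direction``. A stated
    "decrease" unit flips the sign of the slope, so that, e.g., an RR of 0.86
    per 100-g *decrease* in red meat yields RR < 1 for negative deltas.
    """
    rr = float(er_row[rr_column])
    if rr <= 0:
        raise ValidationError("relative risks must be > 0")
    unit = float(er_row["unit_g"])
    beta = np.log(rr) / unit
    if er_row["direction"] == "decrease":
        beta = -beta
    return float(np.exp(beta * delta_g))


def combine_rr(rrs) -> float:
    """Multiplicative combination of several exposures on one disease."""
    out = 1.0
    for rr in rrs:
        if rr <= 0:
            raise ValidationError("relative risks must be > 0")
        out *= float(rr)
    return out


def lag_weight(t, profile: LagProfile):
    """Phase-in weight in [0, 1] at ``t`` years after the dietary change."""
    t = np.asarray(t, dtype=float)
    w = np.where(t < profile.zero_years, 0.0, norm.cdf((t - profile.mean) / profile.sd))
    return float(w) if w.ndim == 0 else w


def rr_schedule(
    deltas: dict[str, float],
    er: pd.DataFrame,
    horizon: int = DEFAULT_HORIZON,
    scenario: str = "central",
) -> pd.DataFrame:
    """Outcome-by-year relative risks with time lags applied.

    ``scenario`` selects the central RRs or the low/high 95% CI bounds.
    Returns a DataFrame indexed by outcome with one column per year
    ``t = 0 .. horizon-1``; ``RR(t) = exp(ln(RR_final) * weight(t))``.
    """
    col = {"central": "rr", "low": "ci_low", "high": "ci_high"}[scenario]
    final = {o: 1.0 for o in OUTCOMES}
    for _, row in er.iterrows():
        d = deltas.get(row["exposure"], 0.0)
        final[row["outcome"]] = combine_rr(
            [final[row["outcome"]], log_linear_rr(row, d, rr_column=col)]
        )
    t = np.arange(horizon, dtype=float)
    out = {}
    for o in OUTCOMES:
        w = lag_weight(t, OUTCOME_LAG[o])
        out[o] = np.exp(np.log(final[o]) * w)
    return pd.DataFrame(out, index=t).T


def _sex_arrays(pop: pd.DataFrame, sex: str):
    grp = pop[pop["sex"] == sex].sort_values("age")
    return (
        grp["population"].values.astype(float),
        grp["all_cause_rate"].values.astype(float),
        grp[list(OUTCOMES)].values.astype(float),  # (ages, outcomes)
    )


def impacted_mortality(
    m_all: np.ndarray, cause: np.ndarray, rr_t: pd.DataFrame
) -> np.ndarray:
    """All-cause mortality schedule under the lagged RRs, shape (ages, years).

    ``m'(a, t) = m(a) - sum_o cause_o(a) * (1 - RR_o(t))``; baseline rates
    are held constant over follow-up.
    """
    rr = rr_t.loc[list(OUTCOMES)].values  # (outcomes, years)
    reduction = cause @ (1.0 - rr)  # (ages, years)
    m = m_all[:, None] - reduction
    if (m < -1e-12).any():
        raise ValidationError("impacted mortality went negative; impossible inputs")
    return np.maximum(m, 0.0)


def _rate_at(m: np.ndarray, age: int, year: int) -> float:
    """Rate lookup with an open-ended top age interval."""
    a = min(age, m.shape[0] - 1)
    if m.ndim == 1:
        return m[a]
    return m[a, min(year, m.shape[1] - 1)]


def cohort_life_expectancy(m, horizon: int = DEFAULT_HORIZON) -> float:
    """Life expectancy at birth of a cohort entering at t=0.

    ``m`` is either a constant-in-time rate vector by age or an (ages, years)
    schedule; the cohort experiences ``m[age=t, t]`` in its t-th year.
    """
    m = np.asarray(m, dtype=float)
    alive = 1.0
    py = 0.0
    for t in range(horizon):
        q = 1.0 - np.exp(-_rate_at(m, t, t))
        deaths = alive * q
        py += alive - deaths / 2.0
        alive -= deaths
    return py


def population_person_years(pop0: np.ndarray, m, horizon: int = DEFAULT_HORIZON) -> np.ndarray:
    """Person-years lived per calendar year by the current population.

    The starting population ``pop0`` (by age, top interval open) is aged
    forward with no in-migration and no births; within-year deaths earn a
    half-year credit.
    """
    m = np.asarray(m, dtype=float)
    n_ages = len(pop0)
    p = pop0.astype(float).copy()
    py = np.zeros(horizon)
    for t in range(horizon):
        rates = m if m.ndim == 1 else m[:n_ages, min(t, m.shape[1] - 1)]
        q = 1.0 - np.exp(-rates)
        deaths = p * q
        py[t] = p.sum() - deaths.sum() / 2.0
        survivors = p - deaths
        new = np.zeros_like(p)
        new[1:] = survivors[:-1]
        new[-1] += survivors[-1]  # open-ended top interval
        p = new
    return py


@dataclass
class HealthImpactResult:
    """Health impact of one pathway relative to the baseline diet."""

    deltas: dict[str, float]
    rr_scenario: str
    life_years_gained_by_year: np.ndarray  # person-years, calendar years 0..H-1
    total_life_years_gained: float
    baseline_le_years: dict[str, float]  # per sex and "combined"
    delta_le_months: dict[str, float]  # per sex, "combined", "combined_mean"
    attribution_fv: float | None = None


def health_impact(
    deltas: dict[str, float],
    pop: pd.DataFrame,
    er: pd.DataFrame | None = None,
    scenario: str = "central",
    horizon: int = DEFAULT_HORIZON,
    birth_sex_ratio: tuple[float, float] = BIRTH_SEX_RATIO,
) -> HealthImpactResult:
    """Run the full life-table comparison for one set of exposure deltas."""
    if er is None:
        er = load_exposure_response()
    pop = validate_population(pop)
    rr_t = rr_schedule(deltas, er, horizon=horizon, scenario=scenario)

    lyg = np.zeros(horizon)
    base_le: dict[str, float] = {}
    delta_le: dict[str, float] = {}
    for sex in ("male", "female"):
        pop0, m_all, cause = _sex_arrays(pop, sex)
        m_imp = impacted_mortality(m_all, cause, rr_t)
        lyg += population_person_years(pop0, m_imp, horizon) - population_person_years(
            pop0, m_all, horizon
        )
        le0 = cohort_life_expectancy(m_all, horizon)
        le1 = cohort_life_expectancy(m_imp, horizon)
        base_le[sex] = le0
        delta_le[sex] = (le1 - le0) * 12.0

    wm, wf = birth_sex_ratio
    base_le["combined"] = (wm * base_le["male"] + wf * base_le["female"]) / (wm + wf)
    delta_le["combined"] = (wm * delta_le["male"] + wf * delta_le["female"]) / (wm + wf)
    delta_le["combined_mean"] = (delta_le["male"] + delta_le["female"]) / 2.0
    return HealthImpactResult(
        deltas=dict(deltas),
        rr_scenario=scenario,
        life_years_gained_by_year=lyg,
        total_life_years_gained=float(lyg.sum()),
        baseline_le_years=base_le,
        delta_le_months=delta_le,
    )


def attribution_fv(
    deltas: dict[str, float],
    pop: pd.DataFrame,
    er: pd.DataFrame | None = None,
    scenario: str = "central",
    horizon: int = DEFAULT_HORIZON,
) -> float | None:
    """Share of the life-expectancy change attributable to fruit/vegetables.

    The model is rerun with the meat deltas zeroed; the attribution is the
    ratio of the sex-combined life-expectancy changes. Returns ``None`` when
    the full-pathway change is zero (the share is undefined).
    """
    full = health_impact(deltas, pop, er, scenario, horizon)
    if full.delta_le_months["combined"] == 0.0:
        return None
    fv_only = dict(deltas, red_meat=0.0, processed_meat=0.0)
    fv = health_impact(fv_only, pop, er, scenario, horizon)
    return fv.delta_le_months["combined"] / full.delta_le_months["combined"]


def sensitivity_bounds(
    deltas: dict[str, float],
    pop: pd.DataFrame,
    er: pd.DataFrame | None = None,
    horizon: int = DEFAULT_HORIZON,
) -> dict[str, HealthImpactResult]:
    """Central / low / high RR scenarios (95% CI bounds applied to every RR)."""
    return {
        scen: health_impact(deltas, pop, er, scenario=scen, horizon=horizon)
        for scen in ("central", "low", "high")
    }
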