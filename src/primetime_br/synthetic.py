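"""Synthetic, internally consistent input bundles.

The real simulation is driven by national data sources (household budget
survey consumption and elasticities, health-survey BMI, burden-of-disease
rates, hospital admission costs, census population) that are not shipped
with the package.  This module generates stand-in bundles with the same
shapes and the same internal consistency guarantees:

* disease surfaces are built by running the three-state cohort model
  forward from parametric (Gompertz-type) incidence and case-fatality
  curves, so the downstream consistency solvers round-trip by
  construction;
* BMI strata are normal distributions calibrated so population obesity
  prevalence matches the reported baselines (~19.8% men, ~23.6% women);
* beverage volumes are scaled so the 20% tax scenario produces the
  reported mean energy-intake changes (~-26.4 kcal/day total, -18.1
  lower-income, -29.0 upper-income).

Elasticity magnitudes are literature-plausible stand-ins (own-price near
-1.1 for soft drinks), not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agegroups import AGE_GROUPS, GROUP_INDEX_BY_AGE, group_means, midpoint
from .bundle import InputBundle
from .demand import DEFAULT_CATEGORIES, ElasticityMatrix, TaxScenario, energy_change
from .disease import (AGES, ALL_DISEASES, FATAL_DISEASES, DiseaseEpi,
                      forward_three_state)
from .lifetable import DiabetesMediation, SimConfig
from .weight import calibrate

INCOMES = ("total", "lower", "upper")
SEXES = ("male", "female")


@dataclass
class FixtureConfig:
    """Calibration anchors and scale of the synthetic bundle."""

    seed: int = 0
    pop_scale: float = 100_000.0           # adults per sex
    obesity_target: dict = field(
        default_factory=lambda: {"male": 0.198, "female": 0.236}
    )
    delta_ei_target: dict = field(
        default_factory=lambda: {"total": -26.4, "lower": -18.1, "upper": -29.0}
    )
    disease_rate_scale: float = 1.0

    def __post_init__(self) -> None:
        for s, v in self.obesity_target.items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"obesity target for {s} must be in (0,1)")


# base seven-category elasticity matrix; rows respond to column prices.
# own-price diagonals negative; sparse cross terms: substitution toward the
# diet category, mild complementarity among sugary drinks.
_BASE_ELASTICITY = np.array(
    [
        [-1.00,  0.15,  0.00,  0.10,  0.00,  0.05,  0.00],
        [ 0.12, -1.10,  0.00,  0.08,  0.00,  0.10,  0.05],
        [ 0.00,  0.10, -0.95,  0.00,  0.12,  0.00,  0.00],
        [ 0.10,  0.08,  0.00, -1.05,  0.00,  0.06,  0.00],
        [ 0.00,  0.05,  0.15,  0.00, -0.90,  0.00,  0.00],
        [ 0.08,  0.30,  0.05,  0.06,  0.04, -0.80,  0.02],
        [ 0.00,  0.10,  0.00,  0.00,  0.00,  0.00, -1.20],
    ]
)
_INCOME_ELASTICITY_SCALE = {"total": 1.0, "lower": 1.10, "upper": 0.95}

# mL/person/day at the reference (young adult male, total income)
_BASE_VOLUMES = {1: 40.0, 2: 110.0, 3: 20.0, 4: 30.0, 5: 15.0, 6: 15.0, 7: 10.0}
_SEX_VOLUME = {"male": 1.15, "female": 0.87}
_INCOME_VOLUME = {"total": 1.0, "lower": 0.80, "upper": 1.12}

# Gompertz-type rate parameters: annual hazard i0*exp(g*(age-20)) etc.
# (i0, g, f0, gf, p20) per disease; sex multipliers on i0 below.
_EPI_PARAMS = {
    "t2dm":          (2.0e-3, 0.045, 2.0e-3, 0.050, 0.005),
    "ihd":           (8.0e-4, 0.055, 1.0e-2, 0.040, 0.001),
    "stroke":        (5.0e-4, 0.055, 1.5e-2, 0.040, 0.0005),
    "hhd":           (2.0e-4, 0.060, 8.0e-3, 0.050, 0.0002),
    "low_back_pain": (1.0e-2, 0.010, 0.0,    0.0,   0.050),
    "hip_oa":        (8.0e-4, 0.040, 0.0,    0.0,   0.002),
    "knee_oa":       (1.5e-3, 0.040, 0.0,    0.0,   0.004),
}
_EPI_SEX_MULT = {
    "t2dm": {"male": 1.0, "female": 0.95},
    "ihd": {"male": 1.6, "female": 0.7},
    "stroke": {"male": 1.2, "female": 0.9},
    "hhd": {"male": 0.8, "female": 1.2},
    "low_back_pain": {"male": 0.85, "female": 1.25},
    "hip_oa": {"male": 0.9, "female": 1.1},
    "knee_oa": {"male": 0.85, "female": 1.25},
}

_RR_TABLE = [
    ("t2dm", 2.00, 1.70, 2.35),
    ("ihd", 1.50, 1.35, 1.67),
    ("stroke", 1.40, 1.25, 1.55),
    ("hhd", 1.70, 1.45, 2.00),
    ("low_back_pain", 1.20, 1.10, 1.30),
    ("hip_oa", 1.30, 1.15, 1.45),
    ("knee_oa", 1.35, 1.20, 1.50),
]

_UTILITY = {
    "t2dm": 0.06, "ihd": 0.08, "stroke": 0.12, "hhd": 0.05,
    "low_back_pain": 0.05, "hip_oa": 0.04, "knee_oa": 0.04,
}

# mean cost per admission (BRL) and admissions per case (annual proportion
# for prevalence-based diseases, one-off proportion for incidence-based)
_COSTS = {
    "t2dm": (1500.0, 0.08), "ihd": (8000.0, 0.90), "stroke": (9000.0, 0.85),
    "hhd": (0.0, 0.0), "low_back_pain": (1200.0, 0.02),
    "hip_oa": (12000.0, 0.70), "knee_oa": (11000.0, 0.60),
}


def _population_weights(sex: str) -> np.ndarray:
    shift = 3.0 if sex == "female" else 0.0   # female survival advantage
    return 1.0 / (1.0 + np.exp((AGES - 62.0 - shift) / 11.0))


def _background_mortality(sex: str) -> np.ndarray:
    scale = 1.0 if sex == "male" else 0.72
    return scale * (5.0e-4 + 2.0e-5 * np.exp(0.100 * (AGES - 20.0)))


def _mean_height(sex: str, mid: float) -> float:
    base = 1.74 if sex == "male" else 1.61
    return base - 0.0009 * max(mid - 30.0, 0.0)


def _bmi_mean_curve(sex: str, mid: float) -> float:
    base = 24.3 if sex == "male" else 24.8
    return base + 4.3 * np.exp(-(((mid - 52.0) / 26.0) ** 2))


def generate_epi_truth(cfg: FixtureConfig) -> dict[tuple[str, str], dict]:
    """Single-year 'true' surfaces per (disease, sex), built forward.

    Returns, per key, incidence/case_fatality inputs plus the prevalence
    and cause-death surfaces produced by :func:`forward_three_state` with
    the shared background mortality.
    """
    out = {}
    a = AGES - 20.0
    for d, (i0, g, f0, gf, p20) in _EPI_PARAMS.items():
        for sex in SEXES:
            i = cfg.disease_rate_scale * i0 * _EPI_SEX_MULT[d][sex] * np.exp(g * a)
            f = f0 * np.exp(gf * a)
            bg = _background_mortality(sex)
            sim = forward_three_state(i, f, bg, initial_prevalence=p20)
            out[(d, sex)] = {
                "incidence": i, "case_fatality": f,
                "prevalence": sim["prevalence"], "cause_deaths": sim["cause_deaths"],
            }
    return out


def _epi_inputs_frame(truth: dict) -> pd.DataFrame:
    rows = []
    for (d, sex), surf in truth.items():
        for measure, key in (
            ("incidence", "incidence"),
            ("prevalence", "prevalence"),
            ("deaths", "cause_deaths"),
        ):
            if d == "hhd" and measure == "incidence":
                continue  # incidence unavailable; inferred downstream
            for g, v in group_means(surf[key]).items():
                rows.append(
                    {"disease": d, "sex": sex, "age_group": g,
                     "measure": measure, "value": v}
                )
    # all-cause mortality: background plus modelled cause-specific deaths
    for sex in SEXES:
        total = _background_mortality(sex).copy()
        for d in ALL_DISEASES:
            total = total + truth[(d, sex)]["cause_deaths"]
        for g, v in group_means(total).items():
            rows.append(
                {"disease": "_all_cause", "sex": sex, "age_group": g,
                 "measure": "deaths", "value": v}
            )
    return pd.DataFrame(rows)


def _consumption_frame(cfg: FixtureConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for sex in SEXES:
        for g in AGE_GROUPS:
            mid = midpoint(g)
            af = max(1.45 - 0.012 * (mid - 20.0), 0.35)
            for income in INCOMES:
                for cid, base in _BASE_VOLUMES.items():
                    jitter = float(np.exp(rng.normal(0.0, 0.03)))
                    rows.append(
                        {"sex": sex, "age_group": g, "income": income,
                         "category": cid,
                         "volume_ml_day": base * af * _SEX_VOLUME[sex]
                         * _INCOME_VOLUME[income] * jitter}
                    )
    return pd.DataFrame(rows)


def _group_pop_weights(population: pd.DataFrame) -> dict[tuple[str, str], float]:
    w = {}
    for sex in SEXES:
        arr = np.zeros(len(AGES))
        sub = population[population["sex"] == sex]
        arr[sub["age"].to_numpy() - AGES[0]] = sub["count"].to_numpy(dtype=float)
        for k, g in enumerate(AGE_GROUPS):
            w[(sex, g)] = float(arr[GROUP_INDEX_BY_AGE == k].sum())
    return w


def _calibrate_consumption(
    consumption: pd.DataFrame,
    elasticities: dict[str, ElasticityMatrix],
    population: pd.DataFrame,
    cfg: FixtureConfig,
) -> pd.DataFrame:
    """Scale each income stratum's volumes so the 20% tax scenario hits the
    target population-mean energy-intake change (linear, hence exact)."""
    scenario = TaxScenario(0.20, 1.0)
    weights = _group_pop_weights(population)
    out = consumption.copy()
    for income, target in cfg.delta_ei_target.items():
        sub = out[out["income"] == income]
        dei = energy_change(scenario, elasticities[income], sub, DEFAULT_CATEGORIES)
        w = np.array([weights[(s, g)] for s, g in zip(dei["sex"], dei["age_group"])])
        mean = float(np.average(dei["delta_kcal_day"], weights=w))
        if mean == 0.0:
            raise ValueError(f"cannot calibrate {income}: zero baseline response")
        out.loc[out["income"] == income, "volume_ml_day"] *= target / mean
    return out


def _bmi_frame(cfg: FixtureConfig, population: pd.DataFrame) -> pd.DataFrame:
    from scipy import optimize

    from .weight import BMIDistribution, prevalence as bmi_prevalence

    weights = _group_pop_weights(population)
    income_offset = {"total": 0.0, "lower": -0.35, "upper": 0.40}
    sd = {"male": 4.2, "female": 4.8}
    rows = []
    for sex in SEXES:
        base_means = {g: _bmi_mean_curve(sex, midpoint(g)) for g in AGE_GROUPS}
        w = np.array([weights[(sex, g)] for g in AGE_GROUPS])
        w = w / w.sum()

        def obesity_gap(shift: float) -> float:
            obs = np.array([
                bmi_prevalence(BMIDistribution(base_means[g] + shift, sd[sex]))["obesity"]
                for g in AGE_GROUPS
            ])
            return float(obs @ w) - cfg.obesity_target[sex]

        shift = optimize.brentq(obesity_gap, -10.0, 10.0, xtol=1e-10)
        for g in AGE_GROUPS:
            for income in INCOMES:
                rows.append(
                    {"sex": sex, "age_group": g, "income": income,
                     "mean_bmi": base_means[g] + shift + income_offset[income],
                     "sd_bmi": sd[sex],
                     "mean_height_m": _mean_height(sex, midpoint(g))}
                )
    return pd.DataFrame(rows)


def make_fixture(cfg: FixtureConfig | None = None) -> InputBundle:
    """Generate a complete, calibrated input bundle."""
    cfg = cfg or FixtureConfig()
    rng = np.random.default_rng(cfg.seed)

    pop_rows = []
    for sex in SEXES:
        w = _population_weights(sex)
        counts = cfg.pop_scale * w / w.sum()
        for age, c in zip(AGES, counts):
            pop_rows.append({"sex": sex, "age": int(age), "count": c})
    population = pd.DataFrame(pop_rows)

    elasticities = {
        income: ElasticityMatrix(
            _BASE_ELASTICITY * _INCOME_ELASTICITY_SCALE[income], stratum=income
        )
        for income in INCOMES
    }
    for mat in elasticities.values():
        mat.validate_signs(DEFAULT_CATEGORIES)
    consumption = _consumption_frame(cfg, rng)
    consumption = _calibrate_consumption(consumption, elasticities, population, cfg)

    bmi = _bmi_frame(cfg, population)
    truth = generate_epi_truth(cfg)
    epi_inputs = _epi_inputs_frame(truth)

    rr = pd.DataFrame(
        [{"disease": d, "rr_per_5bmi": m, "lo95": lo, "hi95": hi}
         for d, m, lo, hi in _RR_TABLE]
    )
    util = pd.DataFrame(
        [{"disease": d, "decrement": v, "sd": 0.2 * v} for d, v in _UTILITY.items()]
    )
    cost_rows = []
    for d, (mean, adm) in _COSTS.items():
        for sex in SEXES:
            for g in AGE_GROUPS:
                jitter = float(np.exp(rng.normal(0.0, 0.05))) if mean > 0 else 1.0
                cost_rows.append(
                    {"disease": d, "sex": sex, "age_group": g,
                     "mean_cost_per_admission": mean * jitter,
                     "sd_cost": 0.5 * mean * jitter,
                     "admissions_per_case": adm}
                )
    costs = pd.DataFrame(cost_rows)

    meta = {
        "seed": int(cfg.seed),
        "tmrel": 22.5,
        "tax_rate": 0.20,
        "pass_through": 1.0,
        "delta_ei_rel_sd": 0.016,
        "decrement_rel_sd": 0.20,
        "cost_cv": 0.50,
        "obesity_target": dict(cfg.obesity_target),
        "delta_ei_target": dict(cfg.delta_ei_target),
    }
    return InputBundle(
        categories=DEFAULT_CATEGORIES,
        elasticities=elasticities,
        consumption=consumption,
        bmi=bmi,
        epi_inputs=epi_inputs,
        population=population,
        relative_risks=rr,
        utilities=util,
        costs=costs,
        mediation=DiabetesMediation(2.0, 1.8, ci_ihd=(1.7, 2.4), ci_stroke=(1.5, 2.2)),
        meta=meta,
    )


def make_null_fixture(cfg: FixtureConfig | None = None) -> InputBundle:
    """A bundle whose elasticities are all zero: the tax moves nothing, so
    the full pipeline must return an identically zero outcome delta."""
    bundle = make_fixture(cfg)
    bundle.elasticities = {
        income: ElasticityMatrix(np.zeros((7, 7)), stratum=income)
        for income in INCOMES
    }
    bundle.meta["null"] = True
    return bundle


def make_toy_lifetable() -> dict:
    """A 3-age, 1-disease cohort small enough to recompute by hand.

    Cohorts of 1000 persons start at ages 20, 21 and 22; one fatal disease
    with constant incidence 0.10/y, case fatality 0.05/y, initial
    prevalence 0.10, and background mortality 0.02/y; three annual cycles.
    The all-cause input equals background plus the modelled cause-specific
    deaths so the engine's background recovery is exact.
    """
    n = len(AGES)
    population = np.zeros(n)
    population[:3] = 1000.0
    incidence = np.full(n, 0.10)
    case_fatality = np.full(n, 0.05)
    prevalence0 = np.full(n, 0.10)
    bg = np.full(n, 0.02)
    epi = DiseaseEpi(
        disease="ihd", sex="male",
        incidence=incidence, prevalence=prevalence0, case_fatality=case_fatality,
    )
    all_cause = bg + prevalence0 * case_fatality
    config = SimConfig(discount_rate=0.05, case_horizon=3, n_cycles=3,
                       diabetes_mediation=False)
    return {
        "population": population,
        "epi": {"ihd": epi},
        "all_cause": all_cause,
        "config": config,
        "decrements": {"ihd": 0.2},
    }
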