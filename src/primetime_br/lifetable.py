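"""Proportional multistate life table with BMI-mediated impact fractions.

The engine follows the PRIMEtime design: a closed cohort per sex and
single year of age is advanced in annual cycles.  Each modelled disease
has its own healthy/diseased(/dead) sub-table sharing the cohort's
background mortality; diseases are independent of each other except that
type 2 diabetes also acts as a risk factor for IHD and stroke.  The
intervention enters as a potential impact fraction (PIF) on disease
incidence, computed from the baseline and shifted BMI distributions and a
log-linear relative risk per 5 BMI units above the TMREL.

QALYs are utility-weighted life-years with additive disease decrements;
costs accrue per prevalent case-year or per incident case depending on
each disease's treatment pattern.  QALYs and costs are discounted to
present value; disease cases averted are counted undiscounted over a
fixed 20-year horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .disease import AGES, AGE_MAX, AGE_MIN, DISEASE_SPECS, DiseaseEpi
from .weight import BMIDistribution

N_AGES = len(AGES)


@dataclass(frozen=True)
class RelativeRisk:
    """Relative risk per 5 kg/m^2 of BMI above the TMREL, log-linear."""

    disease: str
    sex: str
    rr_per_5bmi: float
    reference_bmi: float = 22.5  # TMREL
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.rr_per_5bmi < 0:
            raise ValueError("relative risk must be >= 0")

    def rr_at(self, bmi) -> np.ndarray:
        """RR(b) = rr^(max(b - TMREL, 0)/5); flat below the TMREL."""
        excess = np.maximum(np.asarray(bmi, dtype=float) - self.reference_bmi, 0.0)
        return np.power(self.rr_per_5bmi, excess / 5.0)


@dataclass(frozen=True)
class DiabetesMediation:
    """Diabetes as a risk factor for IHD and stroke."""

    rr_ihd_given_dm: float = 2.0
    rr_stroke_given_dm: float = 1.8
    ci_ihd: tuple[float, float] | None = None
    ci_stroke: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.rr_ihd_given_dm < 0 or self.rr_stroke_given_dm < 0:
            raise ValueError("mediation relative risks must be >= 0")


@dataclass(frozen=True)
class DiscreteBMI:
    """Mass-point BMI distribution, used for exact PIF oracle checks."""

    points: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class SimConfig:
    """Simulation frame: closed 2022 cohort, lifetime QALY/cost horizon
    with annual discounting, 20-year undiscounted case horizon."""

    start_year: int = 2022
    min_age: int = AGE_MIN
    max_age: int = AGE_MAX
    discount_rate: float = 0.05
    case_horizon: int = 20
    ppp_factor: float = 2.531     # BRL per international dollar (2021)
    tmrel: float = 22.5
    n_cycles: int = 120
    diabetes_mediation: bool = True

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount rate must be >= 0")


# --------------------------------------------------------------------------
# Potential impact fraction
# --------------------------------------------------------------------------

_QUAD_N = 1000
_QUAD_LO, _QUAD_HI = 10.0, 60.0


def _mean_rr(dist, rr: RelativeRisk) -> float:
    if isinstance(dist, DiscreteBMI):
        return float(np.dot(rr.rr_at(np.array(dist.points)), np.array(dist.weights)))
    grid = np.linspace(_QUAD_LO, _QUAD_HI, _QUAD_N)
    pdf = dist.pdf(grid)
    vals = rr.rr_at(grid) * pdf
    total = np.trapezoid(pdf, grid)
    if not np.isfinite(total) or total <= 0:
        raise ValueError("BMI density not integrable on the quadrature range")
    return float(np.trapezoid(vals, grid) / total)


def pif(dist0, dist1, rr: RelativeRisk) -> float:
    """Potential impact fraction of shifting BMI from dist0 to dist1.

    ``PIF = (E0[RR] - E1[RR]) / E0[RR]``; positive when the shift lowers
    population risk.  Continuous distributions are integrated by
    1000-point quadrature on [10, 60] kg/m^2; mass-point distributions are
    summed exactly.
    """
    r0 = _mean_rr(dist0, rr)
    r1 = _mean_rr(dist1, rr)
    return (r0 - r1) / r0


def adjusted_incidence(incidence: np.ndarray, pif_by_age: np.ndarray) -> np.ndarray:
    """Apply a PIF schedule: ``i'(a) = i(a) * (1 - PIF(a))``."""
    p = np.asarray(pif_by_age, dtype=float)
    if (p > 1).any():
        raise ValueError("PIF cannot exceed 1")
    return np.asarray(incidence, dtype=float) * (1.0 - p)


def diabetes_adjust(
    incidence: np.ndarray,
    dm_prev_baseline: np.ndarray,
    dm_prev_scenario: np.ndarray,
    rr_given_dm: float,
) -> np.ndarray:
    """Rescale IHD/stroke incidence for a changed diabetes prevalence.

    The population-average risk scales as ``1 + p (RR - 1)``; incidence is
    multiplied by the ratio of scenario to baseline factors.
    """
    if rr_given_dm < 0:
        raise ValueError("RR must be >= 0")
    p0 = np.asarray(dm_prev_baseline, dtype=float)
    p1 = np.asarray(dm_prev_scenario, dtype=float)
    if ((p0 < 0) | (p0 > 1) | (p1 < 0) | (p1 > 1)).any():
        raise ValueError("prevalences must be in [0, 1]")
    # ratio first: when p1 == p0 the factor is exactly 1 and the incidence
    # passes through bitwise unchanged (a null scenario stays exactly null)
    factor = (1.0 + p1 * (rr_given_dm - 1.0)) / (1.0 + p0 * (rr_given_dm - 1.0))
    return np.asarray(incidence, dtype=float) * factor


# --------------------------------------------------------------------------
# Cohort run
# --------------------------------------------------------------------------


@dataclass
class LifeTableRun:
    """State trajectories of one sex's closed cohort.

    ``alive`` has shape (n_cohorts, n_cycles + 1); ``prevalence[d]`` and
    ``cases[d]`` have shape (n_cohorts, n_cycles), prevalence among the
    alive after incidence (mid-cycle) and incident-case counts in persons.
    """

    sex: str
    start_ages: np.ndarray
    population: np.ndarray
    alive: np.ndarray
    life_years: np.ndarray          # (n_cohorts, n_cycles)
    prevalence: dict[str, np.ndarray]
    cases: dict[str, np.ndarray]
    config: SimConfig

    @property
    def initial_adults(self) -> float:
        return float(self.population.sum())

    def conservation_error(self) -> float:
        """Max relative |alive + cumulative dead - initial| over cycles."""
        total0 = self.population.sum()
        deaths = -np.diff(self.alive, axis=1)
        cum_dead = np.cumsum(deaths.sum(axis=0))
        err = np.abs(self.alive[:, 1:].sum(axis=0) + cum_dead - total0)
        return float(err.max() / total0)


def run_cohort(
    epi: dict[str, DiseaseEpi],
    pifs: dict[str, np.ndarray] | None,
    config: SimConfig,
    population: np.ndarray,
    all_cause_mortality: np.ndarray,
    sex: str,
    mediation: DiabetesMediation | None = None,
    baseline_t2dm_prev: np.ndarray | None = None,
) -> LifeTableRun:
    """Advance the closed cohort through annual cycles.

    Parameters
    ----------
    epi
        Consistent single-year surfaces per disease for this sex.
    pifs
        Per disease, an (n_ages, n_cycles) PIF surface indexed by current
        age and cycle (None or missing disease = no intervention effect).
    population
        Cohort counts per starting age 20..100.
    all_cause_mortality
        All-cause mortality rate per age; background mortality is this
        minus the modelled cause-specific mortality, so the baseline run
        reproduces the all-cause input without double counting.
    mediation, baseline_t2dm_prev
        Diabetes-as-risk-factor link: scenario T2DM prevalence is compared
        against the baseline surface to rescale IHD/stroke incidence.
    """
    population = np.asarray(population, dtype=float)
    if population.shape != (N_AGES,):
        raise ValueError("population must cover start ages 20..100")
    diseases = list(epi)
    n_cyc = config.n_cycles

    # background mortality: all-cause net of modelled cause-specific deaths
    all_cause = np.asarray(all_cause_mortality, dtype=float)
    cause = np.zeros(N_AGES)
    for d in diseases:
        cause += epi[d].prevalence * epi[d].case_fatality
    background = np.maximum(all_cause - cause, 1e-8)

    a_idx0 = np.arange(N_AGES)
    alive = np.empty((N_AGES, n_cyc + 1))
    alive[:, 0] = population
    life_years = np.empty((N_AGES, n_cyc))
    prev_out = {d: np.empty((N_AGES, n_cyc)) for d in diseases}
    cases_out = {d: np.empty((N_AGES, n_cyc)) for d in diseases}

    # state: prevalence among alive, initialised from the observed surface
    p = {d: epi[d].prevalence.copy() for d in diseases}

    # T2DM first so the mediation sees the current cycle's prevalence
    ordered = sorted(diseases, key=lambda d: d != "t2dm")

    for t in range(n_cyc):
        a_idx = np.minimum(a_idx0 + t, N_AGES - 1)
        excess = np.zeros(N_AGES)
        p_pool = {}
        for d in ordered:
            i_a = epi[d].incidence[a_idx]
            if pifs is not None and d in pifs:
                i_a = i_a * (1.0 - pifs[d][a_idx, t])
            if (
                mediation is not None
                and d in ("ihd", "stroke")
                and baseline_t2dm_prev is not None
                and "t2dm" in p_pool
            ):
                rr = (
                    mediation.rr_ihd_given_dm
                    if d == "ihd"
                    else mediation.rr_stroke_given_dm
                )
                i_a = diabetes_adjust(
                    i_a, baseline_t2dm_prev[:, t], p_pool["t2dm"], rr
                )
            if (i_a > 50).any():
                raise ValueError(f"adjusted incidence rate diverged for {d}")
            new = (1.0 - p[d]) * -np.expm1(-i_a)
            cases_out[d][:, t] = alive[:, t] * new
            p_pool[d] = p[d] + new
            prev_out[d][:, t] = p_pool[d]
            excess += p_pool[d] * epi[d].case_fatality[a_idx]

        m_tot = background[a_idx] + excess
        alive[:, t + 1] = alive[:, t] * np.exp(-m_tot)
        life_years[:, t] = 0.5 * (alive[:, t] + alive[:, t + 1])

        for d in ordered:
            s_h = np.exp(-background[a_idx])
            s_d = np.exp(-(background[a_idx] + epi[d].case_fatality[a_idx]))
            num = p_pool[d] * s_d
            den = (1.0 - p_pool[d]) * s_h + num
            p[d] = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)

    return LifeTableRun(
        sex=sex,
        start_ages=AGES.copy(),
        population=population,
        alive=alive,
        life_years=life_years,
        prevalence=prev_out,
        cases=cases_out,
        config=config,
    )


# --------------------------------------------------------------------------
# Outcome streams
# --------------------------------------------------------------------------


def qaly_stream(run: LifeTableRun, decrements: dict[str, float]) -> np.ndarray:
    """Utility-weighted life-years per cycle (summed over cohorts).

    The utility weight is ``max(0, 1 - sum_d prev_d * dec_d)`` -- additive
    decrements floored at zero utility.
    """
    missing = set(run.prevalence) - set(decrements)
    if missing:
        raise KeyError(f"missing utility decrements for {sorted(missing)}")
    n_cyc = run.config.n_cycles
    weight = np.ones((N_AGES, n_cyc))
    for d, prev in run.prevalence.items():
        weight -= prev * decrements[d]
    weight = np.maximum(weight, 0.0)
    return (run.life_years * weight).sum(axis=0)


def cost_stream(run: LifeTableRun, cost_per_case: dict[str, np.ndarray]) -> np.ndarray:
    """Healthcare costs (BRL) per cycle.

    ``cost_per_case[d]`` is an array over ages 20..100: the annual cost per
    prevalent case for prevalence-based diseases, or the one-off cost per
    incident case for incidence-based diseases.  Hypertensive heart
    disease carries zero cost by construction of its table.
    """
    n_cyc = run.config.n_cycles
    out = np.zeros(n_cyc)
    a_idx0 = np.arange(N_AGES)
    for d, prev in run.prevalence.items():
        basis = DISEASE_SPECS[d].cost_basis
        unit = np.asarray(cost_per_case.get(d, np.zeros(N_AGES)), dtype=float)
        for t in range(n_cyc):
            a_idx = np.minimum(a_idx0 + t, N_AGES - 1)
            if basis == "prevalence":
                persons = run.life_years[:, t] * prev[:, t]
            else:
                persons = run.cases[d][:, t]
            out[t] += float(persons @ unit[a_idx])
    return out


def discount(stream: np.ndarray, rate: float) -> float:
    """Present value of a yearly stream; the first cycle is undiscounted."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    stream = np.asarray(stream, dtype=float)
    return float(np.sum(stream / (1.0 + rate) ** np.arange(len(stream))))


@dataclass
class OutcomeDelta:
    """Intervention-minus-baseline outcomes for one sex (and income level)."""

    sex: str
    income: str
    adult_population: float
    qaly_gained: float
    qaly_per_million: float
    cost_saving_int: float          # international dollars, PPP-converted
    cost_saving_per_100k: float
    cases_averted: dict[str, float]           # absolute, over the case horizon
    cases_averted_per_100k: dict[str, float]

    def as_flat_dict(self) -> dict[str, float]:
        out = {
            "qaly_per_million": self.qaly_per_million,
            "cost_saving_per_100k": self.cost_saving_per_100k,
        }
        for d, v in self.cases_averted_per_100k.items():
            out[f"cases_averted_per_100k_{d}"] = v
        return out


def compare(
    baseline: LifeTableRun,
    intervention: LifeTableRun,
    config: SimConfig,
    decrements: dict[str, float],
    cost_per_case: dict[str, np.ndarray],
    income: str = "total",
) -> OutcomeDelta:
    """Contrast two runs of the same cohort.

    QALY gains and cost savings are discounted present values over the
    lifetime; cases averted are undiscounted sums over the first
    ``config.case_horizon`` cycles.  Costs are converted from BRL to
    international dollars at the PPP factor.
    """
    if baseline.sex != intervention.sex or not np.allclose(
        baseline.population, intervention.population
    ):
        raise ValueError("runs must share the same cohort")
    rate = config.discount_rate
    qaly0 = discount(qaly_stream(baseline, decrements), rate)
    qaly1 = discount(qaly_stream(intervention, decrements), rate)
    cost0 = discount(cost_stream(baseline, cost_per_case), rate)
    cost1 = discount(cost_stream(intervention, cost_per_case), rate)
    pop = baseline.initial_adults
    horizon = config.case_horizon
    averted = {}
    for d in baseline.cases:
        c0 = baseline.cases[d][:, :horizon].sum()
        c1 = intervention.cases[d][:, :horizon].sum()
        averted[d] = float(c0 - c1)
    return OutcomeDelta(
        sex=baseline.sex,
        income=income,
        adult_population=pop,
        qaly_gained=qaly1 - qaly0,
        qaly_per_million=(qaly1 - qaly0) / pop * 1e6,
        cost_saving_int=(cost0 - cost1) / config.ppp_factor,
        cost_saving_per_100k=(cost0 - cost1) / config.ppp_factor / pop * 1e5,
        cases_averted=averted,
        cases_averted_per_100k={d: v / pop * 1e5 for d, v in averted.items()},
    )
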