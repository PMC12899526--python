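"""Internally consistent chronic-disease epidemiology by single year of age.

Burden-of-disease sources report incidence, prevalence and cause-specific
mortality on 5-year age groups, and the three measures need not be mutually
consistent under an explicit disease model.  This module (a) interpolates
grouped rates to single years of age while preserving each group's mean,
and (b) solves, age by age, for the case-fatality (or incidence) schedule
that makes a three-state healthy/diseased/dead cohort model with zero
remission reproduce the observed prevalence and cause-specific mortality.

The three-state yearly update (:func:`forward_three_state`) is the single
source of truth: both solvers are defined as its inverses, and the
synthetic-data generator builds its surfaces by running it forward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.interpolate import CubicSpline, PchipInterpolator

logger = logging.getLogger(__name__)

AGE_MIN = 20
AGE_MAX = 100  # absorbing: rates at 100 apply to everyone older
AGES = np.arange(AGE_MIN, AGE_MAX + 1)

FATAL_DISEASES = ("t2dm", "ihd", "stroke", "hhd")
NONFATAL_DISEASES = ("low_back_pain", "hip_oa", "knee_oa")
ALL_DISEASES = FATAL_DISEASES + NONFATAL_DISEASES


@dataclass(frozen=True)
class DiseaseSpec:
    """Structural description of one modelled condition.

    Cardiometabolic conditions carry a death state and are costed per
    incident or prevalent case depending on their treatment pattern; the
    musculoskeletal trio is modelled without a disease-specific death
    state.  Remission is structurally zero for all conditions.
    """

    name: str
    has_death_state: bool
    cost_basis: str  # "prevalence" | "incidence"

    remission_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.cost_basis not in ("prevalence", "incidence"):
            raise ValueError(f"unknown cost basis {self.cost_basis!r}")
        if self.remission_rate != 0.0:
            raise ValueError("remission is fixed at zero in this model")


DISEASE_SPECS: dict[str, DiseaseSpec] = {
    "t2dm": DiseaseSpec("t2dm", True, "prevalence"),
    "ihd": DiseaseSpec("ihd", True, "incidence"),
    "stroke": DiseaseSpec("stroke", True, "incidence"),
    "hhd": DiseaseSpec("hhd", True, "incidence"),
    "low_back_pain": DiseaseSpec("low_back_pain", False, "prevalence"),
    "hip_oa": DiseaseSpec("hip_oa", False, "incidence"),
    "knee_oa": DiseaseSpec("knee_oa", False, "incidence"),
}


@dataclass
class DiseaseEpi:
    """Consistent single-year-of-age surfaces for one disease and sex.

    ``incidence`` and ``case_fatality`` are annual rates; ``prevalence`` a
    proportion; all indexed by age 20..100.
    """

    disease: str
    sex: str
    incidence: np.ndarray
    prevalence: np.ndarray
    case_fatality: np.ndarray

    def __post_init__(self) -> None:
        for name in ("incidence", "prevalence", "case_fatality"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != AGES.shape:
                raise ValueError(f"{name} must cover ages 20..100")
            if (arr < 0).any() or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite and >= 0")
            setattr(self, name, arr)
        if (self.prevalence >= 1).any():
            raise ValueError("prevalence must be < 1")


def _group_bounds(age_groups: list[str]) -> list[tuple[int, int]]:
    """Parse '20-24' style labels ('95+' meaning 95..AGE_MAX) into bounds."""
    bounds = []
    for g in age_groups:
        g = str(g).strip()
        if g.endswith("+"):
            lo, hi = int(g[:-1]), AGE_MAX
        else:
            lo_s, hi_s = g.replace("–", "-").split("-")
            lo, hi = int(lo_s), int(hi_s)
        bounds.append((lo, hi))
    return bounds


def smooth_to_single_year(
    group_values: dict[str, float] | "list[tuple[str, float]]",
) -> np.ndarray:
    """Interpolate 5-year-group rates to single years of age 20..100.

    Works on the cumulative schedule: group means define a piecewise-linear
    cumulative curve whose knots are interpolated by a cubic spline (exact
    for polynomial age trends) and differenced back to single-year rates.
    Because the spline passes through the knots, each group's mean is
    preserved exactly.  If the spline produces negative rates the monotone
    PCHIP interpolant is used instead, which guarantees nonnegativity at
    the cost of exact polynomial reproduction.
    """
    items = list(group_values.items()) if isinstance(group_values, dict) else list(group_values)
    labels = [k for k, _ in items]
    vals = np.array([v for _, v in items], dtype=float)
    if (vals < 0).any():
        raise ValueError("group rates must be >= 0")
    bounds = _group_bounds(labels)
    order = np.argsort([b[0] for b in bounds])
    bounds = [bounds[i] for i in order]
    vals = vals[order]
    # coverage check: contiguous groups spanning 20..100
    if bounds[0][0] > AGE_MIN or bounds[-1][1] < AGE_MAX:
        raise ValueError(
            f"age groups must cover {AGE_MIN}..{AGE_MAX}, got "
            f"{bounds[0][0]}..{bounds[-1][1]}"
        )
    for (lo1, hi1), (lo2, _) in zip(bounds, bounds[1:]):
        if lo2 != hi1 + 1:
            raise ValueError(f"missing age group between {hi1} and {lo2}")

    knots_x = [bounds[0][0]]
    knots_y = [0.0]
    for (lo, hi), v in zip(bounds, vals):
        knots_x.append(hi + 1)
        knots_y.append(knots_y[-1] + v * (hi + 1 - lo))
    knots_x = np.asarray(knots_x, dtype=float)
    knots_y = np.asarray(knots_y, dtype=float)

    grid = np.arange(AGE_MIN, AGE_MAX + 2, dtype=float)
    cum = CubicSpline(knots_x, knots_y)(grid)
    rates = np.diff(cum)
    if (rates < -1e-12).any():
        rates = np.diff(PchipInterpolator(knots_x, knots_y)(grid))
    return np.maximum(rates, 0.0)


def forward_three_state(
    incidence: np.ndarray,
    case_fatality: np.ndarray,
    background_mortality: np.ndarray,
    initial_prevalence: float = 0.0,
) -> dict[str, np.ndarray]:
    """Yearly difference-equation cohort run from age 20.

    Update order within a cycle at age ``a``: a fraction ``1-exp(-i)`` of
    the healthy become diseased (counted as incident cases), then the
    healthy die at the background rate and the diseased at background plus
    case fatality; cause-specific deaths are the case-fatality share of
    diseased deaths by competing-risk apportionment.

    Returns arrays over ages 20..100: ``healthy``, ``diseased``, ``dead``
    (start-of-cycle state fractions of the original cohort),
    ``prevalence`` (among the alive), ``cases`` (incident fraction of the
    original cohort during the cycle) and ``cause_deaths`` (per person
    alive at the start of the cycle).
    """
    i = np.asarray(incidence, dtype=float)
    f = np.asarray(case_fatality, dtype=float)
    bg = np.asarray(background_mortality, dtype=float)
    n = len(AGES)
    for arr, name in ((i, "incidence"), (f, "case_fatality"), (bg, "background")):
        if arr.shape != (n,):
            raise ValueError(f"{name} must cover ages 20..100")
        if (arr < 0).any():
            raise ValueError(f"{name} must be >= 0")

    h = np.empty(n); d = np.empty(n); dead = np.empty(n)
    prev = np.empty(n); cases = np.empty(n); cause = np.empty(n)
    h[0], d[0], dead[0] = 1.0 - initial_prevalence, initial_prevalence, 0.0
    for k in range(n):
        prev[k] = d[k] / (h[k] + d[k]) if h[k] + d[k] > 0 else 0.0
        new = h[k] * -np.expm1(-i[k])
        cases[k] = new
        h_after = h[k] - new
        d_pool = d[k] + new
        deaths_h = h_after * -np.expm1(-bg[k])
        mu_d = bg[k] + f[k]
        deaths_d = d_pool * -np.expm1(-mu_d)
        frac_cause = f[k] / mu_d if mu_d > 0 else 0.0
        alive = h[k] + d[k]
        cause[k] = deaths_d * frac_cause / alive if alive > 0 else 0.0
        if k + 1 < n:
            h[k + 1] = h_after - deaths_h
            d[k + 1] = d_pool - deaths_d
            dead[k + 1] = dead[k] + deaths_h + deaths_d
    return {
        "healthy": h, "diseased": d, "dead": dead,
        "prevalence": prev, "cases": cases, "cause_deaths": cause,
    }


def solve_case_fatality(
    incidence: np.ndarray,
    prevalence: np.ndarray,
    cause_mortality: np.ndarray,
    background_mortality: np.ndarray,
) -> np.ndarray:
    """Case-fatality schedule reproducing the cause-specific mortality.

    Walks the cohort forward from the observed prevalence at age 20,
    choosing ``f(a) >= 0`` at each age so the cycle's cause-specific deaths
    per person alive match ``cause_mortality[a]``.  Ages where no
    nonnegative solution exists (cause deaths exceed what the diseased pool
    can produce, or are negative) are clamped to the boundary with a logged
    diagnostic -- real grouped data can be inconsistent in exactly this way.
    """
    i = np.asarray(incidence, dtype=float)
    mc = np.asarray(cause_mortality, dtype=float)
    bg = np.asarray(background_mortality, dtype=float)
    p = np.asarray(prevalence, dtype=float)
    n = len(AGES)
    f = np.zeros(n)
    h, d = 1.0 - p[0], p[0]
    for k in range(n):
        alive = h + d
        new = h * -np.expm1(-i[k])
        d_pool = d + new
        h_after = h - new
        target = mc[k] * alive
        if target <= 0 or d_pool <= 0:
            if target > 0:
                logger.warning(
                    "age %d: positive cause mortality with empty diseased pool; "
                    "case fatality clamped to 0", AGES[k]
                )
            f[k] = 0.0
        else:

            def cause_deaths(fk: float) -> float:
                mu = bg[k] + fk
                return d_pool * -np.expm1(-mu) * (fk / mu if mu > 0 else 0.0)

            hi = 10.0
            if cause_deaths(hi) < target:
                logger.warning(
                    "age %d: cause mortality unattainable; case fatality "
                    "clamped to %.1f", AGES[k], hi
                )
                f[k] = hi
            elif cause_deaths(0.0) >= target:
                f[k] = 0.0
            else:
                f[k] = optimize.brentq(
                    lambda x: cause_deaths(x) - target, 0.0, hi, xtol=1e-12
                )
        mu_d = bg[k] + f[k]
        deaths_h = h_after * -np.expm1(-bg[k])
        deaths_d = d_pool * -np.expm1(-mu_d)
        h = h_after - deaths_h
        d = d_pool - deaths_d
    return f


def infer_incidence(
    prevalence: np.ndarray,
    case_fatality: np.ndarray,
    background_mortality: np.ndarray,
) -> np.ndarray:
    """Incidence schedule whose forward run reproduces the prevalence.

    Under zero remission the age-to-age prevalence update has a closed-form
    inverse for the incidence hazard.  Prevalence trajectories that fall
    faster than differential mortality can explain are infeasible and raise.
    """
    p = np.asarray(prevalence, dtype=float)
    f = np.asarray(case_fatality, dtype=float)
    bg = np.asarray(background_mortality, dtype=float)
    n = len(AGES)
    if (p < 0).any() or (p >= 1).any():
        raise ValueError("prevalence must be in [0, 1)")
    i = np.zeros(n)
    h, d = 1.0 - p[0], p[0]
    for k in range(n - 1):
        s_h = np.exp(-bg[k])
        s_d = np.exp(-(bg[k] + f[k]))
        p_next = p[k + 1]
        # minimum reachable prevalence at zero incidence
        p_min = (d * s_d) / (h * s_h + d * s_d) if (h * s_h + d * s_d) > 0 else 0.0
        if p_next < p_min - 1e-9:
            raise ValueError(
                f"prevalence at age {AGES[k + 1]} falls faster than mortality "
                "can explain under zero remission"
            )
        if h <= 0 or p_next >= 1.0:
            i[k] = 0.0 if h <= 0 else np.inf
            q = 1.0 if h <= 0 else 0.0
        else:
            q = ((h + d) * s_d * (1.0 - p_next)) / (
                h * (p_next * s_h + s_d * (1.0 - p_next))
            )
            q = min(q, 1.0)
            i[k] = -np.log(q) if q > 0 else np.inf
        new = h * (1.0 - q)
        h_after = h - new
        d_pool = d + new
        h = h_after * s_h
        d = d_pool * s_d
    i[n - 1] = i[n - 2]  # terminal age: carry the last solved hazard
    return i
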