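"""Monte Carlo propagation of parametric uncertainty.

Follows standard health-economics conventions for the sampling laws:
relative risks (BMI-disease and diabetes-disease) are lognormal matched to
their 95% CIs, utility decrements truncated-normal on [0, 1], healthcare
costs gamma-distributed multipliers matched to a coefficient of variation,
and the intervention effect (the energy-intake change) a normal
multiplicative scale.  Each run is driven by its own child seed of the
master seed, so results replay bit-identically and baseline/intervention
share draws within a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .bundle import InputBundle
from .pipeline import ParameterDraw

logger = logging.getLogger(__name__)

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class UncertaintySpec:
    """Sampling laws for every uncertain parameter family.

    ``rr_ci`` maps disease -> (lo, hi) 95% CI for the per-5-BMI relative
    risk; degenerate CIs (lo == hi) collapse to the point value.
    ``variance_scale`` multiplies every spread, so 0 reproduces the point
    estimate exactly.
    """

    rr_ci: dict[str, tuple[float, float, float]]   # (point, lo, hi)
    dm_ci: dict[str, tuple[float, float, float]]   # 'ihd'/'stroke'
    decrements: dict[str, tuple[float, float]]     # (mean, sd)
    cost_cv: float = 0.5
    dei_rel_sd: float = 0.016
    n_runs: int = 2000
    seed: int = 0
    variance_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        for d, (_, lo, hi) in {**self.rr_ci, **self.dm_ci}.items():
            if lo > hi:
                raise ValueError(f"CI for {d} has low > high")

    @classmethod
    def from_bundle(
        cls, bundle: InputBundle, n_runs: int = 2000, seed: int = 0,
        variance_scale: float = 1.0,
    ) -> "UncertaintySpec":
        rr_ci = {
            str(r.disease): (float(r.rr_per_5bmi), float(r.lo95), float(r.hi95))
            for r in bundle.relative_risks.itertuples()
        }
        med = bundle.mediation
        dm_ci = {
            "ihd": (med.rr_ihd_given_dm,)
            + (med.ci_ihd or (med.rr_ihd_given_dm, med.rr_ihd_given_dm)),
            "stroke": (med.rr_stroke_given_dm,)
            + (med.ci_stroke or (med.rr_stroke_given_dm, med.rr_stroke_given_dm)),
        }
        dec = {
            str(r.disease): (float(r.decrement), float(r.sd))
            for r in bundle.utilities.itertuples()
        }
        return cls(
            rr_ci=rr_ci, dm_ci=dm_ci, decrements=dec,
            cost_cv=float(bundle.meta.get("cost_cv", 0.5)),
            dei_rel_sd=float(bundle.meta.get("delta_ei_rel_sd", 0.016)),
            n_runs=n_runs, seed=seed, variance_scale=variance_scale,
        )


@dataclass
class IntervalEstimate:
    """Mean and empirical 2.5th-97.5th centiles over Monte Carlo runs."""

    mean: float
    p2_5: float
    p97_5: float

    def __post_init__(self) -> None:
        if self.p2_5 > self.p97_5:
            raise ValueError("lower centile exceeds upper centile")

    def contains(self, x: float) -> bool:
        return self.p2_5 <= x <= self.p97_5

    @property
    def width(self) -> float:
        return self.p97_5 - self.p2_5


def _lognormal_from_ci(
    point: float, lo: float, hi: float, scale: float, rng: np.random.Generator
) -> float:
    if hi <= lo + 1e-15 or scale == 0.0 or point <= 0:
        return point
    sigma = np.log(hi / lo) / (2.0 * Z95) * scale
    median = np.sqrt(lo * hi)
    return float(median * np.exp(rng.normal(0.0, sigma)))


def _truncnorm01(mean: float, sd: float, scale: float, rng: np.random.Generator) -> float:
    sd = sd * scale
    if sd == 0.0:
        return mean
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b))
    return float(mean + sd * stats.norm.ppf(u))


def _gamma_multiplier(cv: float, scale: float, rng: np.random.Generator) -> float:
    cv = cv * scale
    if cv == 0.0:
        return 1.0
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, 1.0 / shape))


def sample(spec: UncertaintySpec, rng: np.random.Generator) -> ParameterDraw:
    """One joint parameter draw; every value is in its valid domain."""
    s = spec.variance_scale
    rr = {
        d: _lognormal_from_ci(pt, lo, hi, s, rng)
        for d, (pt, lo, hi) in spec.rr_ci.items()
    }
    dm_ihd = _lognormal_from_ci(*spec.dm_ci["ihd"], s, rng)
    dm_stroke = _lognormal_from_ci(*spec.dm_ci["stroke"], s, rng)
    dec = {
        d: _truncnorm01(m, sd, s, rng) for d, (m, sd) in spec.decrements.items()
    }
    cost_mult = {d: _gamma_multiplier(spec.cost_cv, s, rng) for d in spec.rr_ci}
    dei_scale = float(rng.normal(1.0, spec.dei_rel_sd * s))
    return ParameterDraw(
        rr=rr,
        rr_ihd_given_dm=dm_ihd,
        rr_stroke_given_dm=dm_stroke,
        decrements=dec,
        cost_mult=cost_mult,
        dei_scale=dei_scale,
    )


def run_mc(
    model: Callable[[ParameterDraw], dict[str, float]],
    spec: UncertaintySpec,
) -> dict[str, IntervalEstimate]:
    """Propagate ``spec`` through ``model`` over ``spec.n_runs`` runs.

    ``model`` maps a parameter draw to a flat {name: value} dict and must
    be deterministic given the draw.  Failed runs are logged and redrawn,
    up to 1% of the run budget; beyond that the analysis aborts.
    Centiles use linear interpolation of order statistics.
    """
    seq = np.random.SeedSequence(spec.seed)
    children = seq.spawn(spec.n_runs + max(1, spec.n_runs // 100))
    results: list[dict[str, float]] = []
    failures = 0
    max_failures = max(1, spec.n_runs // 100)
    k = 0
    while len(results) < spec.n_runs:
        if k >= len(children):
            raise RuntimeError("exhausted redraw budget")
        rng = np.random.default_rng(children[k])
        k += 1
        draw = sample(spec, rng)
        try:
            results.append(model(draw))
        except Exception:
            failures += 1
            logger.exception("Monte Carlo run failed; redrawing")
            if failures > max_failures:
                raise RuntimeError(
                    f"more than {max_failures} Monte Carlo runs failed"
                )
    keys = results[0].keys()
    out = {}
    for key in keys:
        vals = np.array([r[key] for r in results], dtype=float)
        out[key] = IntervalEstimate(
            mean=float(vals.mean()),
            p2_5=float(np.percentile(vals, 2.5)),
            p97_5=float(np.percentile(vals, 97.5)),
        )
    return out
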