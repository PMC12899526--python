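"""Beverage demand response to a price shock.

A tax of rate ``t`` with pass-through ``phi`` raises the consumer price of
every taxed beverage category by ``t * phi``.  Purchased volumes respond
through a matrix of own- and cross-price elasticities estimated for seven
non-alcoholic beverage categories, and the volume response is converted to a
change in daily energy intake using per-category energy densities.

The response model is first order: the proportional volume change of
category *i* is ``sum_j e_ij * dP_j / P_j`` for fixed point elasticities
``e_ij``.  This is the appropriate reduced form for a single, moderate price
change; demand-system curvature is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KCAL_TO_KJ = 4.184
ML_PER_SERVING = 250.0

STRATA_INCOME = ("total", "lower", "upper")


@dataclass(frozen=True)
class BeverageCategory:
    """One beverage category of the demand system.

    ``kcal_per_ml`` is the energy density; diet/light drinks have ~0.
    ``taxed`` marks the categories covered by the excise tax.
    """

    id: int
    name: str
    taxed: bool
    kcal_per_ml: float

    def __post_init__(self) -> None:
        if self.kcal_per_ml < 0:
            raise ValueError(f"energy density must be >= 0, got {self.kcal_per_ml}")


#: The seven-category configuration used throughout: sugar-containing
#: categories are taxed; light/diet soft drinks are untaxed but respond
#: through cross-price elasticities.
DEFAULT_CATEGORIES: tuple[BeverageCategory, ...] = (
    BeverageCategory(1, "sugary juices/drinks", True, 0.45),
    BeverageCategory(2, "soft drinks", True, 0.42),
    BeverageCategory(3, "sugary dairy drinks", True, 0.70),
    BeverageCategory(4, "sweetened juices/drinks", True, 0.40),
    BeverageCategory(5, "sweetened dairy drinks", True, 0.65),
    BeverageCategory(6, "light/diet soft drinks", False, 0.02),
    BeverageCategory(7, "sports/energy drinks", True, 0.30),
)


@dataclass(frozen=True)
class TaxScenario:
    """An ad valorem excise tax: rate 0.20 and full pass-through by default."""

    tax_rate: float = 0.20
    pass_through: float = 1.0

    def __post_init__(self) -> None:
        if self.tax_rate < 0:
            raise ValueError(f"tax rate must be >= 0, got {self.tax_rate}")
        if not 0.0 <= self.pass_through <= 1.0:
            raise ValueError(f"pass-through must be in [0, 1], got {self.pass_through}")

    @property
    def price_shock(self) -> float:
        """Proportional consumer price increase on taxed categories."""
        return self.tax_rate * self.pass_through


@dataclass
class ElasticityMatrix:
    """Own-/cross-price elasticities ``e_ij``: % volume change of category
    *i* per 1% price change of category *j*, for one income stratum."""

    values: np.ndarray
    stratum: str = "total"
    category_ids: Sequence[int] = field(default_factory=lambda: tuple(range(1, 8)))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.category_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"elasticity matrix must be {n}x{n}, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("elasticity matrix contains non-finite entries")

    def row(self, category_id: int) -> np.ndarray:
        try:
            idx = list(self.category_ids).index(category_id)
        except ValueError:
            raise KeyError(
                f"no elasticity row for beverage category {category_id}"
            ) from None
        return self.values[idx]

    def validate_signs(self, categories: Sequence[BeverageCategory]) -> None:
        """Own-price elasticities of taxed sugary categories must be <= 0."""
        for cat in categories:
            if cat.taxed:
                idx = list(self.category_ids).index(cat.id)
                own = self.values[idx, idx]
                if own > 0:
                    raise ValueError(
                        f"own-price elasticity for taxed category "
                        f"{cat.name!r} must be <= 0, got {own}"
                    )


def servings_to_ml(servings: float) -> float:
    """Convert standard beverage servings to millilitres (250 mL/serving)."""
    if servings < 0:
        raise ValueError(f"servings must be >= 0, got {servings}")
    return ML_PER_SERVING * servings


def build_price_change(
    scenario: TaxScenario, categories: Sequence[BeverageCategory]
) -> np.ndarray:
    """Proportional price change per category: ``t*phi`` if taxed, else 0."""
    return np.array(
        [scenario.price_shock if c.taxed else 0.0 for c in categories], dtype=float
    )


def apply_elasticities(
    price_changes: np.ndarray,
    elasticities: ElasticityMatrix,
    baseline: pd.DataFrame,
) -> pd.DataFrame:
    """First-order volume response per stratum.

    Parameters
    ----------
    price_changes
        Proportional price changes, aligned with ``elasticities.category_ids``.
    baseline
        Long-format consumption with columns
        ``sex, age_group, income, category, volume_ml_day``.

    Returns
    -------
    DataFrame with the same stratum columns and ``delta_ml_day``.
    Post-change volumes are floored at zero (with a logged warning), since
    the linear response can otherwise overshoot for heavy price changes.
    """
    price_changes = np.asarray(price_changes, dtype=float)
    ids = list(elasticities.category_ids)
    if price_changes.shape != (len(ids),):
        raise ValueError(
            f"price-change vector length {price_changes.shape} does not match "
            f"{len(ids)} categories"
        )
    missing = set(baseline["category"].unique()) - set(ids)
    if missing:
        raise KeyError(f"no elasticity row for beverage category {sorted(missing)}")
    if (baseline["volume_ml_day"] < 0).any():
        raise ValueError("baseline volumes must be >= 0")

    # proportional volume change per category (same for every stratum)
    rel_change = elasticities.values @ price_changes

    out = baseline.copy()
    pos = out["category"].map({cid: k for k, cid in enumerate(ids)}).to_numpy()
    delta = out["volume_ml_day"].to_numpy() * rel_change[pos]
    floored = np.maximum(delta, -out["volume_ml_day"].to_numpy())
    if (floored > delta).any():
        n_floor = int((floored > delta).sum())
        logger.warning(
            "floored %d post-change volumes at zero (linear overshoot)", n_floor
        )
    out["delta_ml_day"] = floored
    return out


def volume_to_energy(
    volume_changes: pd.DataFrame, categories: Sequence[BeverageCategory]
) -> pd.DataFrame:
    """Convert volume changes to daily energy-intake changes per stratum.

    Returns a DataFrame with columns ``sex, age_group, income,
    delta_kcal_day`` where ``delta_kcal_day = sum_i dV_i * kcal_per_ml_i``.
    """
    density = {c.id: c.kcal_per_ml for c in categories}
    missing = set(volume_changes["category"].unique()) - set(density)
    if missing:
        raise KeyError(f"no energy density for category {sorted(missing)}")
    df = volume_changes.copy()
    df["delta_kcal_day"] = df["delta_ml_day"] * df["category"].map(density)
    out = (
        df.groupby(["sex", "age_group", "income"], as_index=False, observed=True)[
            "delta_kcal_day"
        ]
        .sum()
        .sort_values(["sex", "age_group", "income"], ignore_index=True)
    )
    return out


def energy_change(
    scenario: TaxScenario,
    elasticities: ElasticityMatrix,
    baseline: pd.DataFrame,
    categories: Sequence[BeverageCategory] = DEFAULT_CATEGORIES,
) -> pd.DataFrame:
    """Tax scenario -> per-stratum change in energy intake (kcal/person/day)."""
    dp = build_price_change(scenario, categories)
    dv = apply_elasticities(dp, elasticities, baseline)
    return volume_to_energy(dv, categories)


def energy_change_interval(
    scenario: TaxScenario,
    elasticities: ElasticityMatrix,
    elasticity_se: np.ndarray,
    baseline: pd.DataFrame,
    categories: Sequence[BeverageCategory] = DEFAULT_CATEGORIES,
    n_draws: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Propagate elasticity standard errors to 95% bounds on the energy change.

    Draws each elasticity independently from a normal law centred on its
    point estimate, recomputes the energy change, and reports the empirical
    2.5th/97.5th centiles alongside the point estimate.
    """
    if rng is None:
        rng = np.random.default_rng()
    elasticity_se = np.asarray(elasticity_se, dtype=float)
    if elasticity_se.shape != elasticities.values.shape:
        raise ValueError("standard-error matrix must match the elasticity matrix")
    point = energy_change(scenario, elasticities, baseline, categories)
    draws = np.empty((n_draws, len(point)))
    for k in range(n_draws):
        e_k = ElasticityMatrix(
            elasticities.values + rng.standard_normal(elasticity_se.shape) * elasticity_se,
            stratum=elasticities.stratum,
            category_ids=elasticities.category_ids,
        )
        draws[k] = energy_change(scenario, e_k, baseline, categories)[
            "delta_kcal_day"
        ].to_numpy()
    out = point.copy()
    out["lo95"] = np.percentile(draws, 2.5, axis=0)
    out["hi95"] = np.percentile(draws, 97.5, axis=0)
    return out
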