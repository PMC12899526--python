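"""Five-year adult age groups (20-24 ... 90-94, 95+) shared across modules."""

from __future__ import annotations

import numpy as np

from .disease import AGE_MAX, AGE_MIN, AGES

AGE_GROUPS: tuple[str, ...] = tuple(
    f"{lo}-{lo + 4}" for lo in range(AGE_MIN, 95, 5)
) + ("95+",)


def group_bounds(label: str) -> tuple[int, int]:
    if label.endswith("+"):
        return int(label[:-1]), AGE_MAX
    lo, hi = label.split("-")
    return int(lo), int(hi)


def group_of(age: int) -> str:
    if age >= 95:
        return "95+"
    lo = AGE_MIN + 5 * ((int(age) - AGE_MIN) // 5)
    return f"{lo}-{lo + 4}"


def midpoint(label: str) -> float:
    lo, hi = group_bounds(label)
    return (lo + hi) / 2.0


#: index of each single year of age 20..100 into AGE_GROUPS
GROUP_INDEX_BY_AGE: np.ndarray = np.array(
    [AGE_GROUPS.index(group_of(a)) for a in AGES]
)


def expand_to_ages(values_by_group: dict[str, float]) -> np.ndarray:
    """Step-function expansion of per-group values to single ages 20..100."""
    vals = np.array([values_by_group[g] for g in AGE_GROUPS], dtype=float)
    return vals[GROUP_INDEX_BY_AGE]


def group_means(values_by_age: np.ndarray) -> dict[str, float]:
    """Unweighted mean of a single-year surface within each age group."""
    values_by_age = np.asarray(values_by_age, dtype=float)
    return {
        g: float(values_by_age[GROUP_INDEX_BY_AGE == k].mean())
        for k, g in enumerate(AGE_GROUPS)
    }
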