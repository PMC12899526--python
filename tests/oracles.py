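"""Independent, deliberately naive re-computations used as test oracles.

Everything here is scalar, loop-based, spreadsheet-style arithmetic kept
free of the package's vectorised implementations.
"""

from __future__ import annotations

import math


def three_state_forward(
    i: list[float], f: list[float], bg: list[float], p0: float
) -> dict:
    """Scalar three-state cohort recursion (healthy/diseased/dead)."""
    n = len(i)
    h, d, dead = 1.0 - p0, p0, 0.0
    prev, cases, cause = [], [], []
    for k in range(n):
        alive = h + d
        prev.append(d / alive if alive > 0 else 0.0)
        new = h * (1.0 - math.exp(-i[k]))
        cases.append(new)
        h_after = h - new
        d_pool = d + new
        deaths_h = h_after * (1.0 - math.exp(-bg[k]))
        mu = bg[k] + f[k]
        deaths_d = d_pool * (1.0 - math.exp(-mu))
        cause.append(deaths_d * (f[k] / mu if mu > 0 else 0.0) / alive if alive else 0.0)
        h = h_after - deaths_h
        d = d_pool - deaths_d
        dead += deaths_h + deaths_d
    return {"prevalence": prev, "cases": cases, "cause_deaths": cause,
            "healthy": h, "diseased": d, "dead": dead}


def toy_lifetable(
    pops: list[float],
    i: float,
    f: float,
    bg: float,
    p0: float,
    decrement: float,
    n_cycles: int,
    pif: float = 0.0,
) -> dict:
    """Hand-computable one-disease cohort run mirroring the engine's rules.

    Each cohort: incidence first (on the healthy), then one death draw with
    total hazard ``bg + prev_pool * f``; sub-table survival splits healthy
    (bg) and diseased (bg + f); life-years accrue mid-cycle; utility weight
    is ``1 - prev_pool * decrement``.
    """
    i_eff = i * (1.0 - pif)
    alive = list(pops)
    prev = [p0] * len(pops)
    survivors, cases_by_cycle, qaly, dead_total = [], [], [], 0.0
    for _t in range(n_cycles):
        new_alive, cases_t, qaly_t = [], 0.0, 0.0
        for c in range(len(alive)):
            a, p = alive[c], prev[c]
            new = (1.0 - p) * (1.0 - math.exp(-i_eff))
            cases_t += a * new
            pool = p + new
            m_tot = bg + pool * f
            a_next = a * math.exp(-m_tot)
            ly = 0.5 * (a + a_next)
            qaly_t += ly * max(0.0, 1.0 - pool * decrement)
            s_h = math.exp(-bg)
            s_d = math.exp(-(bg + f))
            num = pool * s_d
            den = (1.0 - pool) * s_h + num
            prev[c] = num / den if den > 0 else 0.0
            dead_total += a - a_next
            new_alive.append(a_next)
        alive = new_alive
        survivors.append(list(alive))
        cases_by_cycle.append(cases_t)
        qaly.append(qaly_t)
    return {
        "survivors": survivors,
        "cases": cases_by_cycle,
        "qaly": qaly,
        "dead_total": dead_total,
    }


def multi_disease_cohort(
    population: list[float],
    incidence: dict,
    case_fatality: dict,
    prev0: dict,
    all_cause: list[float],
    pif: dict,
    n_cycles: int,
) -> dict:
    """Scalar re-implementation of the proportional multistate cohort.

    ``incidence``/``case_fatality``/``prev0`` map disease -> per-age lists
    (ages 20..100 -> indices 0..80); ``pif`` maps disease -> constant PIF.
    Returns incident cases per disease summed over cohorts, per cycle.
    """
    n_ages = len(all_cause)
    diseases = list(incidence)
    bg = []
    for a in range(n_ages):
        excess = sum(prev0[d][a] * case_fatality[d][a] for d in diseases)
        bg.append(max(all_cause[a] - excess, 1e-8))
    alive = list(population)
    p = {d: list(prev0[d]) for d in diseases}
    cases = {d: [0.0] * n_cycles for d in diseases}
    for t in range(n_cycles):
        for c in range(len(alive)):
            a = min(c + t, n_ages - 1)
            pools = {}
            for d in diseases:
                i_eff = incidence[d][a] * (1.0 - pif.get(d, 0.0))
                new = (1.0 - p[d][c]) * (1.0 - math.exp(-i_eff))
                cases[d][t] += alive[c] * new
                pools[d] = p[d][c] + new
            m = bg[a] + sum(pools[d] * case_fatality[d][a] for d in diseases)
            alive[c] *= math.exp(-m)
            for d in diseases:
                s_h = math.exp(-bg[a])
                s_d = math.exp(-(bg[a] + case_fatality[d][a]))
                num = pools[d] * s_d
                den = (1.0 - pools[d]) * s_h + num
                p[d][c] = num / den if den > 0 else 0.0
    return cases


def present_value(stream: list[float], rate: float) -> float:
    return sum(v / (1.0 + rate) ** y for y, v in enumerate(stream))


def pif_mass_points(points0, weights0, points1, weights1, rr, tmrel=22.5) -> float:
    """Enumeration oracle for the potential impact fraction."""
    def mean_rr(pts, wts):
        return sum(
            w * rr ** (max(b - tmrel, 0.0) / 5.0) for b, w in zip(pts, wts)
        )
    r0 = mean_rr(points0, weights0)
    r1 = mean_rr(points1, weights1)
    return (r0 - r1) / r0
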