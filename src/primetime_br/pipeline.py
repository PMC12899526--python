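"""End-to-end scenario evaluation.

``Pipeline`` wires the stages together for one input bundle:

1. tax scenario -> per-stratum change in daily energy intake (demand);
2. energy change -> body-weight trajectory and shifted BMI distribution
   per sex/age-group stratum (energy-balance model);
3. BMI shift -> potential impact fraction per disease and age, phased in
   along the weight trajectory's approach to its new equilibrium;
4. grouped epidemiological inputs -> consistent single-year surfaces
   (smoothing + case-fatality/incidence solvers);
5. baseline and intervention multistate life-table runs -> discounted
   QALY and cost differences and undiscounted cases averted.

The baseline life-table run depends only on the bundle, so it is computed
once and shared across Monte Carlo draws; each draw re-evaluates the
intervention run and both outcome streams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import demand as dm
from .agegroups import AGE_GROUPS, GROUP_INDEX_BY_AGE, midpoint
from .bundle import InputBundle
from .disease import (AGES, ALL_DISEASES, FATAL_DISEASES, DiseaseEpi,
                      infer_incidence, smooth_to_single_year,
                      solve_case_fatality)
from .lifetable import (DiabetesMediation, LifeTableRun, OutcomeDelta,
                        RelativeRisk, SimConfig, compare, pif, run_cohort)
from .weight import (KCAL_TO_KJ, BMIDistribution, HallState,
                     ReferenceIndividual, initialize_balance,
                     shift_distribution, simulate_batch)

logger = logging.getLogger(__name__)

SEXES = ("male", "female")

_RAMP_CYCLES = 10        # PIF phase-in window following the weight trajectory
_WEIGHT_HORIZON = 40.0   # years simulated to take the asymptotic weight change


@dataclass
class ParameterDraw:
    """One joint draw of the uncertain parameters (point values by default)."""

    rr: dict[str, float]
    rr_ihd_given_dm: float
    rr_stroke_given_dm: float
    decrements: dict[str, float]
    cost_mult: dict[str, float] = field(default_factory=dict)
    dei_scale: float = 1.0


def point_draw(bundle: InputBundle) -> ParameterDraw:
    """The draw holding every parameter at its point estimate."""
    rr = dict(
        zip(bundle.relative_risks["disease"],
            bundle.relative_risks["rr_per_5bmi"].astype(float))
    )
    return ParameterDraw(
        rr=rr,
        rr_ihd_given_dm=bundle.mediation.rr_ihd_given_dm,
        rr_stroke_given_dm=bundle.mediation.rr_stroke_given_dm,
        decrements=bundle.decrements(),
        cost_mult={},
        dei_scale=1.0,
    )


class Pipeline:
    """Scenario evaluator bound to one input bundle and simulation frame."""

    def __init__(self, bundle: InputBundle, config: SimConfig | None = None):
        self.bundle = bundle
        self.config = config or SimConfig()
        self.epi: dict[str, dict[str, DiseaseEpi]] = {}
        self.all_cause: dict[str, np.ndarray] = {}
        for sex in SEXES:
            self.epi[sex], self.all_cause[sex] = self._build_epi(sex)
        self._baseline: dict[str, LifeTableRun] = {}
        self._hall_cache: dict[str, list[HallState]] = {}

    # -- stage 4: consistent epidemiology --------------------------------

    def _grouped(self, disease: str, sex: str, measure: str) -> dict[str, float]:
        df = self.bundle.epi_inputs
        sub = df[(df["disease"] == disease) & (df["sex"] == sex)
                 & (df["measure"] == measure)]
        return dict(zip(sub["age_group"], sub["value"].astype(float)))

    def _build_epi(self, sex: str) -> tuple[dict[str, DiseaseEpi], np.ndarray]:
        all_cause = smooth_to_single_year(self._grouped("_all_cause", sex, "deaths"))
        cause = {}
        smoothed = {}
        for d in ALL_DISEASES:
            p = smooth_to_single_year(self._grouped(d, sex, "prevalence"))
            p = np.minimum(p, 1.0 - 1e-9)
            entry = {"prevalence": p}
            inc = self._grouped(d, sex, "incidence")
            if inc:
                entry["incidence"] = smooth_to_single_year(inc)
            if d in FATAL_DISEASES:
                entry["deaths"] = smooth_to_single_year(self._grouped(d, sex, "deaths"))
                cause[d] = entry["deaths"]
            smoothed[d] = entry
        background = np.maximum(
            all_cause - sum(cause.values(), np.zeros(len(AGES))), 1e-8
        )
        epi = {}
        for d, entry in smoothed.items():
            p = entry["prevalence"]
            if d in FATAL_DISEASES:
                if "incidence" in entry:
                    i = entry["incidence"]
                    f = solve_case_fatality(i, p, entry["deaths"], background)
                else:
                    # neither measure alone identifies the model: alternate
                    # the two solvers (damped, capped) until the pair
                    # stabilises, starting from the crude case fatality.
                    # per-age clamp diagnostics are muted during the
                    # intermediate iterations.
                    f = entry["deaths"] / np.maximum(p, 1e-6)
                    dis_logger = logging.getLogger("primetime_br.disease")
                    old_level = dis_logger.level
                    dis_logger.setLevel(logging.ERROR)
                    try:
                        for _ in range(20):
                            i = infer_incidence(p, f, background)
                            f_new = solve_case_fatality(
                                i, p, entry["deaths"], background
                            )
                            f = 0.5 * (f + np.minimum(f_new, 2.0))
                    finally:
                        dis_logger.setLevel(old_level)
                    if (f >= 1.99).any():
                        logger.warning(
                            "%s/%s: case fatality capped at 2/y for %d ages",
                            d, sex, int((f >= 1.99).sum()),
                        )
            else:
                i = entry["incidence"]
                f = np.zeros(len(AGES))
            epi[d] = DiseaseEpi(disease=d, sex=sex, incidence=i,
                                prevalence=p, case_fatality=f)
        return epi, all_cause

    # -- stage 1: demand --------------------------------------------------

    def energy_change(self, scenario: dm.TaxScenario, income: str):
        sub = self.bundle.consumption[self.bundle.consumption["income"] == income]
        if sub.empty:
            raise KeyError(f"no consumption data for income level {income!r}")
        return dm.energy_change(
            scenario, self.bundle.elasticities[income], sub, self.bundle.categories
        )

    # -- stages 2-3: weight response and PIF surfaces ---------------------

    def _hall_states(self, income: str) -> list[HallState]:
        if income not in self._hall_cache:
            states = []
            for sex in SEXES:
                for g in AGE_GROUPS:
                    row = self._bmi_row(sex, g, income)
                    h = float(row["mean_height_m"])
                    ind = ReferenceIndividual(
                        sex=sex, age=min(midpoint(g), 80.0), height=h,
                        weight=float(row["mean_bmi"]) * h * h,
                    )
                    states.append(initialize_balance(ind))
            self._hall_cache[income] = states
        return self._hall_cache[income]

    def _bmi_row(self, sex: str, group: str, income: str):
        b = self.bundle.bmi
        sub = b[(b["sex"] == sex) & (b["age_group"] == group) & (b["income"] == income)]
        if sub.empty:
            raise KeyError(f"no BMI parameters for {sex}/{group}/{income}")
        return sub.iloc[0]

    def weight_response(
        self, scenario: dm.TaxScenario, income: str, dei_scale: float = 1.0
    ) -> dict[str, dict]:
        """Asymptotic weight change and phase-in ramp per (sex, age group)."""
        dei = self.energy_change(scenario, income)
        key = {(s, g): v for s, g, v in
               zip(dei["sex"], dei["age_group"], dei["delta_kcal_day"])}
        states = self._hall_states(income)
        deltas = np.array(
            [key[(sex, g)] for sex in SEXES for g in AGE_GROUPS], dtype=float
        ) * KCAL_TO_KJ * dei_scale
        times, weights = simulate_batch(states, deltas, _WEIGHT_HORIZON)
        dw = weights - weights[:, :1]
        dw_inf = dw[:, -1]
        # an exactly-null intake change is exactly null weight change; the
        # integrator otherwise leaves ~1e-13 kg of float residue that would
        # leak into the PIFs of a null scenario
        dw[deltas == 0.0] = 0.0
        dw_inf = dw[:, -1]
        mid_t = np.arange(_RAMP_CYCLES) + 0.5
        ramp = np.ones((len(states), _RAMP_CYCLES))
        for k in range(len(states)):
            if dw_inf[k] != 0.0:
                ramp[k] = np.interp(mid_t, times, dw[k]) / dw_inf[k]
        out = {}
        k = 0
        for sex in SEXES:
            out[sex] = {}
            for g in AGE_GROUPS:
                out[sex][g] = {"dw_inf": float(dw_inf[k]), "ramp": ramp[k]}
                k += 1
        return out

    def pif_surfaces(
        self,
        scenario: dm.TaxScenario,
        income: str,
        draw: ParameterDraw,
    ) -> dict[str, dict[str, np.ndarray]]:
        """(n_ages, n_cycles) PIF surface per sex and disease."""
        response = self.weight_response(scenario, income, draw.dei_scale)
        n_cyc = self.config.n_cycles
        out = {}
        for sex in SEXES:
            out[sex] = {}
            static = np.zeros((len(ALL_DISEASES), len(AGE_GROUPS)))
            ramps = np.ones((len(AGE_GROUPS), n_cyc))
            for gi, g in enumerate(AGE_GROUPS):
                row = self._bmi_row(sex, g, income)
                dist0 = BMIDistribution(float(row["mean_bmi"]), float(row["sd_bmi"]))
                resp = response[sex][g]
                dist1 = shift_distribution(
                    dist0, resp["dw_inf"], float(row["mean_height_m"])
                )
                ramps[gi, :_RAMP_CYCLES] = np.clip(resp["ramp"], 0.0, 1.0)
                for di, d in enumerate(ALL_DISEASES):
                    rr = RelativeRisk(
                        d, sex, draw.rr[d],
                        reference_bmi=float(self.bundle.meta.get("tmrel", 22.5)),
                    )
                    static[di, gi] = pif(dist0, dist1, rr)
            for di, d in enumerate(ALL_DISEASES):
                by_age = static[di][GROUP_INDEX_BY_AGE]          # (n_ages,)
                out[sex][d] = by_age[:, None] * ramps[GROUP_INDEX_BY_AGE, :]
        return out

    # -- stage 5: life table ----------------------------------------------

    def baseline_run(self, sex: str) -> LifeTableRun:
        if sex not in self._baseline:
            self._baseline[sex] = run_cohort(
                epi=self.epi[sex],
                pifs=None,
                config=self.config,
                population=self.bundle.population_array(sex),
                all_cause_mortality=self.all_cause[sex],
                sex=sex,
            )
        return self._baseline[sex]

    def intervention_run(
        self, sex: str, pifs: dict[str, np.ndarray], draw: ParameterDraw
    ) -> LifeTableRun:
        base = self.baseline_run(sex)
        mediation = None
        baseline_prev = None
        if self.config.diabetes_mediation:
            mediation = DiabetesMediation(
                draw.rr_ihd_given_dm, draw.rr_stroke_given_dm
            )
            baseline_prev = base.prevalence["t2dm"]
        return run_cohort(
            epi=self.epi[sex],
            pifs=pifs,
            config=self.config,
            population=self.bundle.population_array(sex),
            all_cause_mortality=self.all_cause[sex],
            sex=sex,
            mediation=mediation,
            baseline_t2dm_prev=baseline_prev,
        )

    def evaluate(
        self,
        scenario: dm.TaxScenario | None = None,
        income: str = "total",
        draw: ParameterDraw | None = None,
        discount_rate: float | None = None,
    ) -> dict[str, OutcomeDelta]:
        """Full scenario evaluation; returns an OutcomeDelta per sex."""
        scenario = scenario or dm.TaxScenario(
            float(self.bundle.meta.get("tax_rate", 0.20)),
            float(self.bundle.meta.get("pass_through", 1.0)),
        )
        draw = draw or point_draw(self.bundle)
        config = self.config
        if discount_rate is not None:
            config = replace(config, discount_rate=discount_rate)
        surfaces = self.pif_surfaces(scenario, income, draw)
        out = {}
        for sex in SEXES:
            base = self.baseline_run(sex)
            inter = self.intervention_run(sex, surfaces[sex], draw)
            costs = self.bundle.cost_per_case(sex, draw.cost_mult)
            out[sex] = compare(
                base, inter, config, draw.decrements, costs, income=income
            )
        return out

    def outcome_vector(
        self,
        scenario: dm.TaxScenario | None = None,
        income: str = "total",
        draw: ParameterDraw | None = None,
    ) -> dict[str, float]:
        """Flat {name: value} view of :meth:`evaluate`, for Monte Carlo."""
        deltas = self.evaluate(scenario, income, draw)
        out = {}
        for sex, delta in deltas.items():
            for k, v in delta.as_flat_dict().items():
                out[f"{sex}.{k}"] = v
        return out
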