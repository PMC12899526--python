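"""Body-weight dynamics under a sustained change in energy intake.

Implements the adult energy-balance compartment model of Hall and
colleagues: body weight is decomposed into fat mass, lean tissue, glycogen
(with its bound water) and extracellular fluid.  A sustained change in
energy intake perturbs energy expenditure through tissue maintenance costs,
the thermic effect of food, adaptive thermogenesis, and the cost of tissue
turnover; the imbalance is partitioned between fat and lean tissue along
the Forbes body-composition curve.

Two well-known reduced-form properties of the model serve as validation
oracles here:

* a sustained change of 100 kJ/day moves equilibrium body weight by about
  1 kg (``equilibrium_weight_change``), and
* roughly half of the eventual change is reached near one year and ~95%
  near three years.

Glycogen and extracellular fluid equilibrate within days, so they are
treated quasi-statically; fat, lean mass, and adaptive thermogenesis are
integrated with a fixed-step RK4 scheme at weekly resolution.

The module also carries the parametric BMI distributions used to translate
per-stratum weight changes into overweight/obesity prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

KCAL_TO_KJ = 4.184
DAYS_PER_YEAR = 365.25

# -- Hall (adult) model constants, internal unit kJ/day --------------------
RHO_F = 39_500.0          # energy density of fat tissue, kJ/kg
RHO_L = 7_600.0           # energy density of lean tissue, kJ/kg
RHO_G = 17_600.0          # energy density of glycogen, kJ/kg
GAMMA_F = 13.4            # fat maintenance cost, kJ/kg/day
GAMMA_L = 92.0            # lean maintenance cost, kJ/kg/day
ETA_F = 750.0             # fat synthesis/turnover cost, kJ/kg
ETA_L = 960.0             # lean synthesis/turnover cost, kJ/kg
BETA_TEF = 0.10           # thermic effect of food, fraction of dEI
BETA_AT = 0.14            # adaptive thermogenesis, fraction of dEI
TAU_AT_DAYS = 14.0        # adaptive-thermogenesis time constant, days
FORBES_C = 10.4 * RHO_L / RHO_F   # Forbes partition constant, ~2.0 kg
GLYCOGEN_INIT = 0.5       # baseline glycogen store, kg
WATER_PER_GLYCOGEN = 2.7  # kg bound water per kg glycogen
CARB_FRACTION = 0.5       # fraction of energy intake from carbohydrate
XI_NA = 3000.0            # renal sodium excretion constant, mg/L/day
XI_CI = 4000.0            # sodium-response to carbohydrate restriction, mg/day
ECF_FRACTION = 0.22       # extracellular fluid as fraction of body weight

#: Reduced-form equilibrium rule: kJ/day of sustained intake change per kg
#: of eventual body-weight change.
RHO_RULE_KJ_PER_KG = 100.0

#: Physical activity level of the reference adult: the sedentary reference
#: configuration of the energy-balance model (sustained unchanged activity).
DEFAULT_PAL = 1.5


@dataclass(frozen=True)
class ReferenceIndividual:
    """Anthropometry of the representative adult for one stratum."""

    sex: str                     # "male" | "female"
    age: float                   # years
    height: float                # m
    weight: float                # kg
    physical_activity_level: float = DEFAULT_PAL

    def __post_init__(self) -> None:
        if not 1.2 < self.height < 2.2:
            raise ValueError(f"height {self.height} m outside plausible range")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.physical_activity_level < 1.0:
            raise ValueError("physical activity level must be >= 1")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")

    @property
    def bmi(self) -> float:
        return self.weight / self.height**2


@dataclass
class HallState:
    """Energy-balance state at baseline equilibrium.

    Masses in kg; ``adaptive_thermogenesis`` in kJ/day.  Derived constants
    (baseline intake, activity coefficient, the constant expenditure term)
    are carried so that the simulation is self-contained.
    """

    fat_mass: float
    lean_mass: float
    glycogen: float
    extracellular_fluid: float
    adaptive_thermogenesis: float
    baseline_intake: float        # kJ/day
    activity_coeff: float         # kJ/kg/day
    const_expenditure: float      # kJ/day
    height: float                 # m

    @property
    def body_weight(self) -> float:
        return (
            self.fat_mass
            + self.lean_mass
            + (1.0 + WATER_PER_GLYCOGEN) * self.glycogen
            + self.extracellular_fluid
        )


@dataclass
class WeightTrajectory:
    """Weight and BMI over time from intervention start (years)."""

    times: np.ndarray
    weights: np.ndarray
    bmi: np.ndarray

    @property
    def delta_weights(self) -> np.ndarray:
        return self.weights - self.weights[0]

    def at(self, t: float) -> float:
        """Interpolated body weight at time ``t`` years."""
        return float(np.interp(t, self.times, self.weights))


def _fat_fraction(sex: str, age: float, bmi: float) -> float:
    """Baseline body-fat fraction from sex, age and BMI (Jackson-type
    regression, as used in energy-balance microsimulation)."""
    if sex == "male":
        pct = 0.14 * age + 37.31 * np.log(bmi) - 103.94
    else:
        pct = 0.14 * age + 39.96 * np.log(bmi) - 102.01
    return float(np.clip(pct, 5.0, 60.0)) / 100.0


def resting_metabolic_rate(ind: ReferenceIndividual) -> float:
    """Mifflin–St Jeor resting metabolic rate, kJ/day."""
    kcal = 10.0 * ind.weight + 625.0 * ind.height - 5.0 * ind.age
    kcal += 5.0 if ind.sex == "male" else -161.0
    return kcal * KCAL_TO_KJ


def initialize_balance(ind: ReferenceIndividual) -> HallState:
    """Construct the equilibrium state for a reference adult.

    By construction, simulating the returned state with ``delta_EI = 0``
    holds body weight exactly constant: the constant expenditure term is
    calibrated so baseline intake equals baseline expenditure.
    """
    fat = _fat_fraction(ind.sex, ind.age, ind.bmi) * ind.weight
    ecf = ECF_FRACTION * ind.weight
    glyc = GLYCOGEN_INIT
    lean = ind.weight - fat - (1.0 + WATER_PER_GLYCOGEN) * glyc - ecf
    if lean <= 0:
        raise ValueError(
            f"nonphysical anthropometry: derived lean mass {lean:.1f} kg <= 0"
        )
    rmr = resting_metabolic_rate(ind)
    pal = ind.physical_activity_level
    intake = pal * rmr
    # activity cost per kg body weight, net of the thermic effect of food
    delta = ((1.0 - BETA_TEF) * pal - 1.0) * rmr / ind.weight
    const = intake - GAMMA_F * fat - GAMMA_L * lean - delta * ind.weight
    return HallState(
        fat_mass=fat,
        lean_mass=lean,
        glycogen=glyc,
        extracellular_fluid=ecf,
        adaptive_thermogenesis=0.0,
        baseline_intake=intake,
        activity_coeff=delta,
        const_expenditure=const,
        height=ind.height,
    )


def _quasi_static_pools(state: HallState, delta_ei: float) -> tuple[float, float]:
    """Glycogen and extracellular fluid at their fast equilibria for the
    perturbed carbohydrate intake (both settle within days)."""
    ci_b = CARB_FRACTION * state.baseline_intake
    ci = max(ci_b + CARB_FRACTION * delta_ei, 0.0)
    glyc = GLYCOGEN_INIT * np.sqrt(ci / ci_b)
    # carbohydrate-driven sodium/fluid shift, litres ~ kg
    ecf = state.extracellular_fluid - (XI_CI / XI_NA) * (1.0 - ci / ci_b)
    return float(glyc), float(ecf)


def _derivatives(
    fat: float,
    lean: float,
    at: float,
    state: HallState,
    delta_ei: float,
    glyc: float,
    ecf: float,
) -> tuple[float, float, float]:
    """Right-hand side for (fat, lean, adaptive thermogenesis), per day."""
    bw = fat + lean + (1.0 + WATER_PER_GLYCOGEN) * glyc + ecf
    intake = state.baseline_intake + delta_ei
    tef = BETA_TEF * delta_ei
    available = (
        intake
        - state.const_expenditure
        - GAMMA_F * fat
        - GAMMA_L * lean
        - state.activity_coeff * bw
        - tef
        - at
    )
    p = FORBES_C / (FORBES_C + fat)
    denom = 1.0 + (1.0 - p) * ETA_F / RHO_F + p * ETA_L / RHO_L
    eb = available / denom
    dfat = (1.0 - p) * eb / RHO_F
    dlean = p * eb / RHO_L
    dat = (BETA_AT * delta_ei - at) / TAU_AT_DAYS
    return dfat, dlean, dat


def simulate(
    state: HallState,
    delta_ei: float,
    horizon: float,
    step: float = 1.0 / 52.0,
) -> WeightTrajectory:
    """Integrate the energy-balance model under a sustained intake change.

    Parameters
    ----------
    state
        Equilibrium state from :func:`initialize_balance`.
    delta_ei
        Sustained change in energy intake, kJ/day (negative = reduction).
    horizon, step
        Simulation horizon and fixed RK4 step, both in years.  Steps above
        one week destabilise the adaptive-thermogenesis dynamics.
    """
    if step > 1.0 / 52.0 + 1e-12:
        raise ValueError("step must be <= 1/52 year for stability")
    glyc, ecf = _quasi_static_pools(state, delta_ei)
    n = int(round(horizon / step))
    h_days = step * DAYS_PER_YEAR

    fat, lean, at = state.fat_mass, state.lean_mass, state.adaptive_thermogenesis
    times = np.arange(n + 1) * step
    weights = np.empty(n + 1)
    weights[0] = state.body_weight  # report the pre-perturbation weight at t=0

    def f(y):
        return np.array(_derivatives(y[0], y[1], y[2], state, delta_ei, glyc, ecf))

    y = np.array([fat, lean, at], dtype=float)
    for k in range(1, n + 1):
        k1 = f(y)
        k2 = f(y + 0.5 * h_days * k1)
        k3 = f(y + 0.5 * h_days * k2)
        k4 = f(y + h_days * k3)
        y = y + (h_days / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)) or y[0] < 0 or y[1] < 0:
            raise RuntimeError(
                "energy-balance integration diverged; use a smaller step"
            )
        weights[k] = y[0] + y[1] + (1.0 + WATER_PER_GLYCOGEN) * glyc + ecf

    bmi = weights / state.height**2
    return WeightTrajectory(times=times, weights=weights, bmi=bmi)


def simulate_batch(
    states: "list[HallState]",
    delta_eis: np.ndarray,
    horizon: float,
    step: float = 1.0 / 52.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate many independent strata simultaneously.

    Same scheme as :func:`simulate` but with the state vectorised across
    strata, which keeps repeated pipeline evaluations (one per Monte Carlo
    draw) cheap.  Returns ``(times, weights)`` with ``weights`` of shape
    ``(n_strata, n_steps + 1)``.
    """
    if step > 1.0 / 52.0 + 1e-12:
        raise ValueError("step must be <= 1/52 year for stability")
    m = len(states)
    delta_eis = np.asarray(delta_eis, dtype=float)
    if delta_eis.shape != (m,):
        raise ValueError("one delta_EI per state required")
    glyc = np.empty(m); ecf = np.empty(m)
    for k, (st, dei) in enumerate(zip(states, delta_eis)):
        glyc[k], ecf[k] = _quasi_static_pools(st, dei)
    fat = np.array([s.fat_mass for s in states])
    lean = np.array([s.lean_mass for s in states])
    at = np.array([s.adaptive_thermogenesis for s in states])
    intake0 = np.array([s.baseline_intake for s in states])
    delta_c = np.array([s.activity_coeff for s in states])
    const = np.array([s.const_expenditure for s in states])
    inert = (1.0 + WATER_PER_GLYCOGEN) * glyc + ecf

    n = int(round(horizon / step))
    h_days = step * DAYS_PER_YEAR
    times = np.arange(n + 1) * step
    weights = np.empty((m, n + 1))
    weights[:, 0] = np.array([s.body_weight for s in states])

    def f(y):
        fat_, lean_, at_ = y
        bw = fat_ + lean_ + inert
        available = (
            intake0 + delta_eis - const
            - GAMMA_F * fat_ - GAMMA_L * lean_
            - delta_c * bw - BETA_TEF * delta_eis - at_
        )
        p = FORBES_C / (FORBES_C + fat_)
        eb = available / (1.0 + (1.0 - p) * ETA_F / RHO_F + p * ETA_L / RHO_L)
        return np.stack([
            (1.0 - p) * eb / RHO_F,
            p * eb / RHO_L,
            (BETA_AT * delta_eis - at_) / TAU_AT_DAYS,
        ])

    y = np.stack([fat, lean, at])
    for k in range(1, n + 1):
        k1 = f(y)
        k2 = f(y + 0.5 * h_days * k1)
        k3 = f(y + 0.5 * h_days * k2)
        k4 = f(y + h_days * k3)
        y = y + (h_days / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        weights[:, k] = y[0] + y[1] + inert
    if not np.all(np.isfinite(weights)):
        raise RuntimeError("energy-balance integration diverged; use a smaller step")
    return times, weights


def equilibrium_weight_change(delta_ei: float) -> float:
    """Reduced-form asymptotic weight change: ``delta_EI / 100`` kg per kJ/day.

    This is the model's one-line summary (100 kJ/day per kg) and serves as
    an independent oracle for :func:`simulate`.
    """
    return delta_ei / RHO_RULE_KJ_PER_KG


def reduced_form_trajectory(
    delta_ei: float, times: np.ndarray, half_time: float = 1.0
) -> np.ndarray:
    """Exponential reduced form ``dw(t) = dw_inf * (1 - 2^(-t/tau))``, kg."""
    dw_inf = equilibrium_weight_change(delta_ei)
    return dw_inf * (1.0 - np.power(2.0, -np.asarray(times, dtype=float) / half_time))


# --------------------------------------------------------------------------
# BMI distributions and prevalence
# --------------------------------------------------------------------------

OVERWEIGHT_CUT = 25.0
OBESITY_CUT = 30.0


@dataclass(frozen=True)
class BMIDistribution:
    """Parametric BMI distribution for one (sex, age group, income) cell.

    ``family`` is ``"normal"`` (default) or ``"lognormal"``; for the
    lognormal family ``mean``/``sd`` are still the distribution's mean and
    standard deviation on the BMI scale.
    """

    mean: float
    sd: float
    family: str = "normal"
    stratum: tuple = ()

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")

    def _frozen(self):
        if self.family == "normal":
            return stats.norm(self.mean, self.sd)
        sigma2 = np.log1p((self.sd / self.mean) ** 2)
        mu = np.log(self.mean) - 0.5 * sigma2
        return stats.lognorm(np.sqrt(sigma2), scale=np.exp(mu))

    def cdf(self, x) -> np.ndarray:
        return self._frozen().cdf(x)

    def pdf(self, x) -> np.ndarray:
        return self._frozen().pdf(x)


def shift_distribution(
    dist: BMIDistribution, delta_weight: float, mean_height: float
) -> BMIDistribution:
    """Location-shift the BMI distribution by ``delta_weight / height^2``.

    The spread is left unchanged: the stratum-wide weight change moves
    every individual's BMI by the same amount.
    """
    if not np.isfinite(delta_weight):
        raise ValueError("delta_weight must be finite")
    return replace(dist, mean=dist.mean + delta_weight / mean_height**2)


def prevalence(dist: BMIDistribution) -> dict[str, float]:
    """Overweight (25 <= BMI < 30) and obesity (BMI >= 30) proportions."""
    f25 = float(dist.cdf(OVERWEIGHT_CUT))
    f30 = float(dist.cdf(OBESITY_CUT))
    return {"overweight": f30 - f25, "obesity": 1.0 - f30}


def calibrate(
    target_mean: float,
    target_obesity: float,
    family: str = "normal",
    stratum: tuple = (),
) -> BMIDistribution:
    """Fit the dispersion so the distribution hits a mean/obesity pair.

    For the normal family the solution is closed form:
    ``sd = (30 - mean) / z`` with ``z`` the upper-``target_obesity``
    standard-normal quantile.  When the mean sits exactly at the obesity
    cut-point any sd reproduces obesity 0.5; the smallest-sd convention
    (sd -> a nominal 1e-6-consistent floor) applies, implemented as sd=1.
    """
    if not 0.0 < target_obesity < 1.0:
        raise ValueError("target obesity must be in (0, 1)")
    if family == "normal":
        z = stats.norm.ppf(1.0 - target_obesity)
        if abs(z) < 1e-12:
            if abs(target_mean - OBESITY_CUT) > 1e-9:
                raise ValueError(
                    "obesity 0.5 requires the mean at the cut-point 30"
                )
            return BMIDistribution(target_mean, 1.0, family, stratum)
        sd = (OBESITY_CUT - target_mean) / z
        if sd <= 0:
            raise ValueError(
                f"infeasible target pair (mean {target_mean}, "
                f"obesity {target_obesity}) for the normal family"
            )
        return BMIDistribution(target_mean, sd, family, stratum)
    # lognormal: solve for sd numerically
    def gap(sd: float) -> float:
        d = BMIDistribution(target_mean, sd, "lognormal", stratum)
        return prevalence(d)["obesity"] - target_obesity

    try:
        sd = optimize.brentq(gap, 1e-6, 30.0, xtol=1e-12)
    except ValueError as exc:
        raise ValueError("infeasible target pair for the lognormal family") from exc
    return BMIDistribution(target_mean, sd, "lognormal", stratum)
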