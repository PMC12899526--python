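# Methods

This note records the model structure, the defaults and why they were
chosen, the numerical choices, and what the synthetic data do and do not
establish.

## Scenario frame

A closed cohort of adults (ages 20–100, by sex and single year of age)
starts in 2022; no entries thereafter. The intervention is a 20% ad
valorem excise tax on sugar-containing beverages with 100% pass-through to
consumer prices, in place for the cohort's lifetime. QALYs and healthcare
costs accrue over the remaining lifetime and are discounted at 5%/year
(0% and 10% as sensitivity); disease cases are counted undiscounted over a
20-year horizon. Costs are converted from BRL to international dollars at
the 2021 PPP factor 2.531.

## Demand response

Seven beverage categories; categories 1–5 and 7 (sugar-containing) are
taxed, light/diet soft drinks are untaxed but respond through
cross-elasticities. Taxability is a per-category flag, so other
configurations are possible. The volume response is first order in the
price change — fixed point elasticities applied to a single 20% shock —
so doubling all price changes doubles all responses exactly; demand-system
curvature is out of scope. Post-change volumes are floored at zero (a
physical constraint the linear model lacks) with a logged warning.
Serving counts convert to volume at 250 mL/serving.

Confidence bounds on the energy-intake change, when requested, come from
Monte Carlo over user-supplied elasticity standard errors (independent
normal perturbations), since no analytic propagation is prescribed.

## Body-weight dynamics

The adult energy-balance model tracks fat mass F, lean mass L, glycogen G
(with 2.7 kg bound water per kg), extracellular fluid, and adaptive
thermogenesis AT. Energy available for tissue change is intake minus
maintenance (γ_F = 13.4, γ_L = 92 kJ/kg/day), physical activity
(δ·weight), the thermic effect of food (10% of ΔEI) and AT (14% of ΔEI,
14-day time constant), divided by 1 + (1−p)η_F/ρ_F + p·η_L/ρ_L to account
for turnover costs (η_F = 750, η_L = 960 kJ/kg). The fat/lean partition
follows the Forbes curve, p = C/(C+F) with C = 10.4·ρ_L/ρ_F ≈ 2.0 kg;
tissue energy densities ρ_F = 39.5, ρ_L = 7.6 MJ/kg.

Initialisation: body-fat fraction from the Jackson-type regression on sex,
age and BMI; extracellular fluid 22% of body weight; glycogen 0.5 kg;
resting metabolic rate by Mifflin–St Jeor; baseline intake = PAL × RMR
with PAL 1.5 (the model's sedentary reference; activity is held fixed
under the intervention). The constant expenditure term is calibrated so
baseline intake equals expenditure — a zero intake change holds weight
constant by construction.

Numerics: glycogen and extracellular fluid have day-scale time constants,
so they are set to their quasi-static equilibria for the perturbed
carbohydrate intake (carbohydrate share 0.5 of energy); fat, lean and AT
are integrated by fixed-step RK4 at weekly steps (the AT eigenvalue caps
the stable step near one week; larger steps are rejected). The reduced
form — equilibrium change ΔEI/100 kg per kJ/day, exponential approach
with one-year half-time — is exposed separately as a validation oracle.
For the reference adult at −100 kJ/day the full model reaches its
asymptote of ≈ −1.1 kg with ~58% of the change at one year and ~92% at
three. No trajectory with positively-weighted exponential modes can show
both exactly 50% at one year and 95% at three (the remaining fraction is
log-convex), so the model is validated against both stated anchors with
±10-point bands.

Population weight change is computed per stratum (sex × 5-year age group ×
income) from that stratum's mean-BMI reference individual (group-midpoint
age, capped at 80 for the body-fat regression; sex-specific mean height
from the input table). Within-stratum heterogeneity of response is
ignored: one ΔEI per stratum. BMI distributions are normal by default
(lognormal available) and are location-shifted by Δw/h² with unchanged
spread; overweight is F(30)−F(25), obesity 1−F(30).

## Disease inputs

Grouped rates (5-year age groups 20–24 … 90–94, 95+) are interpolated to
single years on the cumulative schedule: a cubic spline through the
piecewise-linear cumulative knots (exact for polynomial age trends,
group means preserved exactly), falling back to monotone PCHIP whenever
the spline would produce a negative rate. Age 100 is absorbing.

Each disease follows a three-state model (healthy → diseased → dead; zero
remission; no death state for the musculoskeletal trio). The yearly
update applies incidence to the healthy first (incident fraction
1−e^(−i)), then background mortality to all and case fatality to the
diseased, with competing-risk apportionment of diseased deaths.

Case fatality is solved age-by-age (bracketed root-finding) so the
forward run reproduces the cause-specific mortality; infeasible ages
(cause deaths exceeding what the diseased pool can produce) clamp to the
boundary with a logged diagnostic — the behaviour real, mutually
inconsistent grouped data trigger. Incidence, where unavailable, is the
closed-form inverse of the prevalence update. For hypertensive heart
disease neither measure is supplied alone, so the two solvers alternate
(damped by ½, case fatality capped at 2/year) for 20 iterations; on
consistent surfaces this recovers the generating rates to well under 2%
except at the extreme ages, where pools are tiny.

Background mortality is all-cause minus the modelled causes'
prevalence-weighted case fatality (floored at 10⁻⁸), so the baseline run
reproduces the all-cause input without double counting.

## Life table and outcomes

Per cycle: incidence (PIF-adjusted, diabetes-mediated for IHD and stroke)
updates each sub-table; total mortality is background plus the sum of
prevalence-weighted case fatalities; life-years accrue mid-cycle
(half-cycle correction). Sub-tables are proportional: each disease's
survival split ignores the others' excess mortality. The diabetes
mediation compares the scenario's T2DM prevalence with the baseline run's
at the same cohort and cycle, so a null scenario passes through bitwise
unchanged.

PIFs are computed per sex × age group from the baseline and shifted BMI
distributions by 1000-point trapezoidal quadrature on [10, 60] kg/m²
(mass-point distributions are summed exactly); TMREL 22.5 kg/m²,
log-linear RR per 5 BMI units above it, flat below. The PIF phases in
over the first 10 cycles following the stratum's weight trajectory
(evaluated at cycle midpoints), then holds for life.

QALY weights are 1 minus the sum of prevalence-weighted utility
decrements, floored at zero. Costs: per prevalent case-year (T2DM, low
back pain) or one-off per incident case (IHD, stroke, osteoarthritis),
with hypertensive heart disease costed at zero (its cost inputs are not
reliably attributable). Cases averted are incident cases (not prevalent
case-years) summed undiscounted over the 20-year horizon. Runs span 120
cycles so even the youngest cohort is exhausted; mass balance holds to
< 10⁻⁹ relative error by construction.

Income-level scenarios reuse the same epidemiological surfaces with
income-specific consumption, elasticities and BMI distributions; the
sources do not provide income-specific disease rates.

## Uncertainty

Lognormal relative risks matched to 95% CIs (median = √(lo·hi)),
truncated-normal utility decrements on [0,1], gamma cost multipliers
(mean 1, CV 0.5), normal multiplicative intervention-effect scale
(SD 1.6%, from the reported CI width of the energy-intake change).
Default 2000 runs; each run has its own child seed of the master seed, so
replays are bit-identical and baseline/intervention share draws within a
run. Failed runs are redrawn up to 1% of the budget. Intervals are
empirical 2.5th/97.5th centiles with linear interpolation of order
statistics. The acceptance suite exercises a 200-run configuration, which
the package treats as its standard scaled-down sensitivity check.

## Synthetic data

The generator builds bundles that are internally consistent by
construction: disease surfaces come from forward runs of the three-state
model with Gompertz-type incidence and case-fatality curves (so the
consistency solvers round-trip); BMI strata are normal distributions whose
population-weighted obesity matches the baseline targets exactly (additive
mean shift solved by root-finding); beverage volumes are scaled per income
stratum so the 20% tax reproduces the target mean energy-intake changes
exactly (the response is linear in volumes). Elasticity magnitudes are
literature-plausible stand-ins (own-price ≈ −1.1 for soft drinks), not
estimates. Small seeded lognormal jitter on volumes and cost means makes
bundles seed-dependent without breaking calibration.

What the synthetic bundles do **not** emulate: survey microdata (weights,
strata, PSUs), secular trends in consumption or disease rates, income- or
region-specific epidemiology, multimorbidity, and any real magnitudes of
costs or utilities. Passing tests therefore establish the correctness and
internal consistency of the machinery — conservation, oracle equivalence,
calibration, orderings — not the absolute Brazilian estimates, which
require the restricted national inputs.

## Known limitations

- First-order demand response; no substitution toward untaxed foods
  outside the seven beverage categories, no revenue side.
- One representative individual per stratum for the weight model.
- Additive utility decrements; no multimorbidity interaction.
- Public-sector admission costs only; dental caries and BMI-related
  cancers excluded.
- The deterministic consistency solver replaces Bayesian rate estimation;
  epidemiological-rate uncertainty is not propagated (parameter
  uncertainty enters only through risks, utilities, costs and the
  intervention effect).
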