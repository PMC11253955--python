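# Methods

This note documents the models, the parameter choices, and the design
decisions behind `ssbtax`, in the order the pipeline runs them.

## Demand estimation

Prices are unit values: household expenditure divided by quantity for each
of 11 food/beverage categories.  A household with zero purchases in a
category has no observed price; its price regressor is imputed as the
median observed price of the smallest enclosing region with at least
`impute_min_obs` (default 5) observations — metro area within state, then
state, then the national median.  "Neighbouring region" has no canonical
definition in household budget surveys; the enclosing-region escalation is
our choice because it is deterministic, order-free and respects the survey
design hierarchy.

Each beverage category's regression is a survey-weighted WLS of log
quantity on the 11 log prices interacted with income-tertile indicators,
income and squared income (in thousands of currency units, for numerical
conditioning; a log-income variant is available via
`ElasticitySpec(income_in_logs=True)`), and household-head controls.
Households with zero purchases of the *dependent* category are excluded
from that regression only (log of zero); they still contribute price
observations elsewhere.  Income tertiles are computed with survey weights.

Standard errors default to cluster-robust on socioeconomic status, which
is how the published Brazilian table is labelled, but with only 3 clusters
those SEs are fragile (they can collapse far below the sampling noise);
the package warns and exposes `cov_type="HC1"` for heteroskedasticity-
robust SEs, which the recovery tests use.

## Tax scenarios

Caloric change per person: Δ = kcal₀ · rate · pass-through · elasticity,
with elasticities applied uniformly within tertile and linearity across
rates (Δ at 30% is exactly 1.5 × Δ at 20%).  Pass-through defaults to
100% — the standard assumption in the SSB modelling literature — and is
configurable in (0, 1.5].  Substitution adds the cross-elasticity terms of
the non-taxed beverages; with the Brazilian estimates the net cross effect
is negative in kcal (alcohol is a complement), so substitution slightly
*deepens* the caloric reduction.  Post-tax intake of every category is
truncated at zero kcal (never binding at the default elasticities and
rates).

## Anthropometric bias correction

Bias at probability p is the difference between the measured-survey and
self-reported survey quantile functions, computed on a grid of 99 equally
spaced probabilities 0.01–0.99 (survey-weighted quantiles, heights in
meters) and smoothed with a cubic smoothing spline whose penalty is chosen
by generalized cross-validation (`scipy.interpolate.make_smoothing_spline`);
a fixed penalty can be supplied for exact reproducibility.  Each
self-reported value is shifted by the spline evaluated at its own quantile;
outside the grid the bias is extrapolated flat.  Weight and height are
corrected independently, by sex — the known limitation that independent
marginal corrections do not guarantee a correct joint BMI distribution is
accepted, and quantified in tests only as a direction check (correction
must raise prevalence when weight is under-reported and height
over-reported).

## Weight dynamics

The adult energy-balance ODE model of Hall et al. (Lancet 2011) tracks
fat mass, lean mass, glycogen (with 2.7 kg bound water per kg), extra-
cellular fluid, and adaptive thermogenesis.  All constants are transcribed
in `src/ssbtax/data/hall_parameters.yaml` with units and provenance;
nothing is fitted.  Notable choices:

* **Initialisation at energy balance.**  Baseline intake equals
  PAL × RMR (Mifflin–St Jeor), PAL defaults to the sedentary 1.5, and the
  constant expenditure offset is solved so a zero intake change yields an
  exactly flat 10-year trajectory.  Initial fat mass follows the
  sex-specific body-fat regression used by the Hall model; baseline
  extracellular fluid is approximated as 45% of total body water (60%/50%
  of body weight for men/women) — it only shifts the lean/ECF split, which
  is absorbed into the calibrated offset.
* **Forbes partition.**  The lean share of the energy imbalance is
  p = C/(C+F) with C = 10.4 · ρ_L/ρ_F ≈ 2.0 kg — the energy-partition form
  of the Forbes mass relation dL/dF = 10.4/F.  (Quoting 10.4 kg directly in
  the energy form is a common transcription error that makes ~70% of
  weight change lean mass; the correct form gives the physiological ~30%.)
* **Integration.**  Deterministic fixed-step classical RK4 at dt = 1 day,
  vectorised across the cohort as one ndarray ODE.  The stiffest time
  constants (glycogen and fluid, ~1 day) are well resolved; tests verify
  agreement within 0.01 kg over 10 years against scipy's adaptive RK45
  (max step 1 day) and against a brute-force Euler integration at
  dt = 0.1 day.  A per-person adaptive loop would be ~100× slower for
  cohorts and no more accurate at these scales.
* The caloric change is applied as a step at t = 0 and sustained; weight,
  height and physical activity are otherwise held constant over the
  horizon.
* **Aggregated mode.**  For sensitivity analysis the model can be run on
  group-average individuals (conventionally 14 groups: sex × age band,
  with the two younger bands split by SES tertile and 60+ pooled); tests
  check self-consistency with the microsimulation means.

A useful scale check: the model yields a 10-year weight change of
0.03–0.05 kg per sustained kcal/day across the adult anthropometry range,
so a ~17 kcal/day reduction moves mean weight by roughly −0.8 kg.

## Outcomes and costs

Baseline obesity prevalence is frozen at its year-0 value (steady-state
assumption); scenario prevalence is the weighted share of simulated
BMI ≥ 30 read at 365-day marks.  Cases averted multiply the absolute
prevalence reduction by a projected adult population; the shipped
projection is a stand-in compounding 147.9 M adults (2021) at 1.2%/yr,
chosen to match published demographic growth for Brazilian adults.  The
year-10 "cases averted" is a stock (prevalence difference × that year's
population), not a cumulative person-year count; the yearly ledger makes
the alternative auditable.

Cost per obesity case = (annual overweight+obesity cost × obesity share) /
prevalent cases, inflated 2019→2021 by an explicit CPI factor
(≈ 1.0392).  Savings are cases averted × cost per case, zeroed for the
first 3 years (average lag of obesity-related morbidity/mortality
benefits) and discounted at 5%/yr with an end-of-year convention to year 0
(the convention is configurable; discounting from year 1 vs year 4 is an
open choice in this literature, and the ledger exposes both factors).
The direct/indirect split scales the total by the cost shares, so the two
components sum exactly to the total.

Bootstrap uncertainty resamples individuals with replacement (keeping
survey weights).  Because every stage is deterministic per individual,
resampling persons together with their already-simulated trajectories is
mathematically identical to re-running the scenario and weight stages per
replicate, and ~100× faster; confidence intervals are seeded percentile
intervals.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* the estimators rely on:
log-log price–quantity responses with tertile-specific embedded
elasticities, independent Bernoulli zero-purchase thinning (45% for
beverages, 20% for foods), right-skewed lognormal income, positive survey
weights summing exactly to the represented population, regional price
variation (state × metro effects, sd 0.10 on log price), and a residual
sd of 0.5 on log quantity.  Adults carry zero-inflated gamma SSB intake
whose sex × age × tertile means follow the published group means
(tertile anchors 53.5/74.0/86.7 kcal/day), lognormal BMI by sex calibrated
so corrected obesity prevalence is ≈ 25.2% (women 28.8%, men 21.2%), and
linear self-report bias (weight under-reported, height over-reported,
larger in women).  Mean kcal/day of the non-taxed beverages is not
published at tertile level; the defaults (unsweetened 55, alcoholic 45,
diet ≈ 1) are realistic picks for Brazilian adults, so with-substitution
totals are direction checks, not exact reproductions.

Not emulated: item-level purchases (categories only), intra-household
purchase correlation, spatial price structure beyond the region effects,
within-person day-to-day intake variance, age trends in BMI, and the full
POF sampling design.  Passing tests therefore demonstrate that the
*estimators and simulators* are correct under known conditions — not that
the synthetic data match every marginal of the real surveys.

## Problem sizes

Defaults used by tests and the acceptance script: 20,000 households for
elasticity estimation (50–100 seeded replicates for recovery rates),
4,000–5,000 adults for the cohort pipeline, 10-year horizon at daily
integration steps, 100–500 bootstrap replicates.  These sizes give
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

Single 24-h recall taken at face value; elasticities applied uniformly
within tertile; constant cost per case over the horizon (population aging
ignored); steady-state baseline prevalence despite the rising Brazilian
trend; adults (20+) only; no tax-revenue or life-table disease modelling.
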