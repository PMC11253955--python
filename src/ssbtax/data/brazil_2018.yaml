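# Published reference inputs for the Brazilian adult population, 2017-2021.
#
# Sources (public aggregate figures, not microdata):
#   - Beverage price elasticities by household income tertile, estimated from
#     the POF 2017-2018 purchase file (survey-weighted log-log demand
#     regressions, SEs clustered on socioeconomic status).
#   - Baseline beverage caloric intake of adults (20+) from the POF 2017-2018
#     single 24-h recall, by sex, age group and income tertile, with the
#     represented population of each stratum (millions of persons).
#   - Obesity prevalence (self-report adjusted to PNS 2019 measured
#     anthropometry) and annual obesity cost figures for Brazil.
#
# These numbers are *inputs* to the arithmetic stages of the pipeline
# (paper-constants mode); the estimation stages reproduce their structure on
# synthetic data.

elasticities:
  # own/cross price elasticity of each beverage category w.r.t. the SSB price,
  # by income tertile (low, middle, high); se and p from the same regressions.
  ssb:
    value: [-1.241, -1.186, -1.126]
    se: [0.015, 0.019, 0.022]
    p: [0.001, 0.001, 0.001]      # printed as <0.001
    n_observations: 18876
  unsweetened:
    value: [0.046, 0.030, 0.066]
    se: [0.017, 0.021, 0.025]
    p: [0.006, 0.150, 0.007]
    n_observations: 27488
  alcoholic:
    value: [-0.122, -0.076, -0.141]
    se: [0.053, 0.047, 0.048]
    p: [0.022, 0.108, 0.003]
    n_observations: 4263
  diet:
    value: [-0.174, 0.094, 0.201]
    se: [0.124, 0.110, 0.084]
    p: [0.160, 0.397, 0.018]
    n_observations: 383

baseline_intake:
  # SSB kcal/person/day and represented population (millions), adults 20+.
  total: {population_m: 147.9, kcal_day: 71.8}
  by_sex:
    female: {population_m: 78.2, kcal_day: 65.1}
    male: {population_m: 69.6, kcal_day: 79.5}
  by_age:
    "20-39": {population_m: 62.2, kcal_day: 92.2}
    "40-59": {population_m: 53.9, kcal_day: 62.9}
    "60+": {population_m: 31.7, kcal_day: 46.9}
  by_tertile:
    low: {population_m: 47.4, kcal_day: 53.5}
    middle: {population_m: 49.1, kcal_day: 74.0}
    high: {population_m: 51.4, kcal_day: 86.7}

obesity:
  # prevalence of BMI >= 30 among adults, self-report adjusted to measured
  # reference (fraction), and the self-reported / measured comparators.
  prevalence_adjusted: 0.252
  prevalence_self_reported: 0.169
  prevalence_measured: 0.268
  by_sex: {female: 0.288, male: 0.212}
  by_tertile: {low: 0.223, middle: 0.262, high: 0.270}
  baseline_cases_m: 37.2        # persons with obesity, millions, 2018

costs:
  # annual societal cost of overweight+obesity for Brazil, 2019 US$.
  total_ow_ob_cost_usd: 38.76e9
  direct_cost_usd: 16.19e9
  indirect_cost_usd: 22.57e9
  obesity_share: 0.87           # share of overweight+obesity cost due to obesity
  inflation_factor_2019_2021: 1.039232   # CPI, maps 906.92 -> 942.5 US$/case
  discount_rate: 0.05
  lag_years: 3
  horizon_years: 10
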