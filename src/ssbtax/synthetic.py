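"""Synthetic POF/PNS-like microdata with known ground truth.

The real Brazilian surveys behind this analysis (the POF 2017-2018 household
budget survey and the PNS 2019 health survey) are not publicly linkable at
the individual level.  This module generates microdata with the same
structure and *embedded, known* parameters so that every downstream stage —
demand estimation, intake aggregation, bias correction, weight simulation —
can be tested for parameter recovery:

* households whose log purchase quantities respond to log prices with
  tertile-specific elasticities chosen by the caller, with independent
  Bernoulli zero-purchase thinning and right-skewed per-capita income;
* adults with beverage kcal/day whose group means follow configurable
  sex x age x income-tertile targets, and with sex-specific reporting bias
  on weight and height (women under-report weight and over-report height
  more than men);
* a yearly adult population projection.

All draws come from one :class:`numpy.random.Generator` seeded from the
config; identical configs give bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import (
    ALL_CATEGORIES,
    BEVERAGE_CATEGORIES,
    SEXES,
    AGE_GROUPS,
    TAXED_CATEGORY,
)
from .errors import ConfigurationError
from .reference import beverage_tables, brazil_reference

# ---------------------------------------------------------------------------
# household purchase generator
# ---------------------------------------------------------------------------

#: default own-price elasticity of the taxed category per income tertile
_DEFAULT_OWN = (-1.241, -1.186, -1.126)

#: default cross elasticities (w.r.t. SSB price) of the other beverages
_DEFAULT_CROSS = {
    "unsweetened": (0.046, 0.030, 0.066),
    "alcoholic": (-0.122, -0.076, -0.141),
    "diet": (-0.174, 0.094, 0.201),
}


@dataclass
class HouseholdConfig:
    """Study conditions for the purchase-file generator.

    Defaults embed the published Brazilian elasticities so the generated
    data mirror the estimation target of the demand module.
    """

    n_households: int = 20_000
    seed: int = 0
    represented_households: float = 59_783_430.0
    #: own-price elasticity of the taxed category, per income tertile
    own_elasticity_by_tertile: tuple[float, float, float] = _DEFAULT_OWN
    #: elasticity of each non-taxed category w.r.t. the SSB price, per tertile
    cross_elasticities: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_CROSS)
    )
    #: own-price elasticity applied to every non-taxed category
    own_elasticity_other: float = -0.8
    #: location/scale of log unit prices (currency per kg or L)
    price_log_location: float = 0.8
    price_log_scale: float = 0.30
    #: sd of regional (state x metro) log-price effects
    region_price_sd: float = 0.10
    #: probability of observing zero purchases, per category
    zero_purchase_prob: dict[str, float] = field(
        default_factory=lambda: {c: (0.45 if c in BEVERAGE_CATEGORIES else 0.2) for c in ALL_CATEGORIES}
    )
    #: residual sd of log quantity around the demand equation
    noise_sd: float = 0.5
    #: per-capita income (thousand currency units): lognormal parameters
    income_log_mean: float = 0.2
    income_log_sd: float = 0.8
    #: linear and quadratic income coefficients in the demand equation
    income_coefs: tuple[float, float] = (0.08, -0.004)
    n_states: int = 5
    metros_per_state: int = 3

    def validate(self) -> None:
        if self.n_households < 1:
            raise ConfigurationError("n_households", "must be >= 1")
        if len(self.own_elasticity_by_tertile) != 3 or not all(
            math.isfinite(e) for e in self.own_elasticity_by_tertile
        ):
            raise ConfigurationError("own_elasticity_by_tertile", "needs 3 finite values")
        for cat, vals in self.cross_elasticities.items():
            if cat not in ALL_CATEGORIES:
                raise ConfigurationError("cross_elasticities", f"unknown category '{cat}'")
            if not all(math.isfinite(v) for v in vals):
                raise ConfigurationError("cross_elasticities", f"non-finite value for '{cat}'")
        for cat, p in self.zero_purchase_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("zero_purchase_prob", f"'{cat}' = {p} outside [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd", "must be >= 0")
        if self.represented_households <= 0:
            raise ConfigurationError("represented_households", "must be > 0")


def weighted_tertiles(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Assign 1/2/3 by survey-weighted tertiles of `values`."""
    order = np.argsort(values, kind="stable")
    cw = np.cumsum(weights[order])
    cw = cw / cw[-1]
    tert_sorted = np.searchsorted([1 / 3, 2 / 3], cw, side="left") + 1
    out = np.empty(len(values), dtype=int)
    out[order] = tert_sorted
    return out


def generate_households(cfg: HouseholdConfig) -> pd.DataFrame:
    """Generate a weekly purchase file of `cfg.n_households` households.

    Returns a wide DataFrame with one row per household: sociodemographics,
    survey weight, region codes, and ``qty_<cat>`` / ``exp_<cat>`` columns
    for the 11 food and beverage categories.  Quantities satisfy the log-log
    demand system with the configured elasticities; a Bernoulli-thinned
    fraction of households records zero purchases (and zero expenditure) in
    each category.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_households

    state = rng.integers(0, cfg.n_states, n)
    metro = rng.integers(0, cfg.metros_per_state, n)

    income = rng.lognormal(cfg.income_log_mean, cfg.income_log_sd, n)  # thousands
    weights = rng.gamma(5.0, 1.0, n)
    weights = weights * (cfg.represented_households / weights.sum())
    tert = weighted_tertiles(income, weights)

    head_gender = rng.integers(0, 2, n)
    schooling = rng.integers(0, 17, n)
    race = rng.integers(0, 5, n)
    marital = rng.integers(0, 2, n)
    n_members = 1 + rng.poisson(1.8, n)
    n_children = np.minimum(rng.poisson(0.8, n), n_members - 1)

    # regional log-price effects per (state, metro, category)
    region_fx = rng.normal(0.0, cfg.region_price_sd, (cfg.n_states, cfg.metros_per_state, len(ALL_CATEGORIES)))

    log_price = np.empty((n, len(ALL_CATEGORIES)))
    for j, cat in enumerate(ALL_CATEGORIES):
        log_price[:, j] = (
            cfg.price_log_location
            + region_fx[state, metro, j]
            + rng.normal(0.0, cfg.price_log_scale, n)
        )

    eta1, eta2 = cfg.income_coefs
    idx_ssb = ALL_CATEGORIES.index(TAXED_CATEGORY)
    own_by_tert = np.asarray(cfg.own_elasticity_by_tertile)

    data = {
        "household_id": np.arange(n),
        "state": state,
        "metro": metro,
        "income_pc": income,
        "survey_weight": weights,
        "income_tertile": tert,
        "head_gender": head_gender,
        "head_schooling": schooling,
        "head_race": race,
        "head_marital": marital,
        "n_members": n_members,
        "n_children": n_children,
    }

    controls = (
        0.05 * head_gender
        + 0.01 * schooling
        - 0.02 * marital
        + 0.08 * n_members
        - 0.03 * n_children
    )

    for j, cat in enumerate(ALL_CATEGORIES):
        logq = 1.5 + eta1 * income + eta2 * income**2 + controls
        if cat == TAXED_CATEGORY:
            logq = logq + own_by_tert[tert - 1] * log_price[:, j]
        else:
            logq = logq + cfg.own_elasticity_other * log_price[:, j]
            if cat in cfg.cross_elasticities:
                cross = np.asarray(cfg.cross_elasticities[cat])
                logq = logq + cross[tert - 1] * log_price[:, idx_ssb]
        logq = logq + rng.normal(0.0, cfg.noise_sd, n)
        qty = np.exp(logq)
        nonzero = rng.random(n) >= cfg.zero_purchase_prob.get(cat, 0.0)
        qty = np.where(nonzero, qty, 0.0)
        price = np.exp(log_price[:, j])
        data[f"qty_{cat}"] = qty
        data[f"exp_{cat}"] = qty * price

    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# individual (24-h recall + anthropometry) generator
# ---------------------------------------------------------------------------


def _sex_age_tertile_multipliers() -> tuple[dict[str, float], dict[str, float]]:
    """Default sex and age intake multipliers from the published group means."""
    ref = brazil_reference()["baseline_intake"]
    total = ref["total"]["kcal_day"]
    sex_mult = {s: ref["by_sex"][s]["kcal_day"] / total for s in SEXES}
    age_mult = {a: ref["by_age"][a]["kcal_day"] / total for a in AGE_GROUPS}
    return sex_mult, age_mult


@dataclass
class BiasModel:
    """Sex-specific self-reporting bias, linear in the true value.

    self-reported weight = true - (w_intercept + w_slope * (true - 60));
    self-reported height = true + h_shift.  Defaults reproduce the
    well-documented pattern of weight under-report and height over-report,
    larger in women.
    """

    weight_intercept: dict[str, float] = field(
        default_factory=lambda: {"female": 1.0, "male": 0.5}
    )
    weight_slope: dict[str, float] = field(
        default_factory=lambda: {"female": 0.020, "male": 0.012}
    )
    height_shift: dict[str, float] = field(
        default_factory=lambda: {"female": 0.015, "male": 0.008}
    )

    @classmethod
    def zero(cls) -> "BiasModel":
        z = {s: 0.0 for s in SEXES}
        return cls(weight_intercept=dict(z), weight_slope=dict(z), height_shift=dict(z))


@dataclass
class IndividualConfig:
    """Study conditions for the adult (20+) recall/anthropometry generator."""

    n_individuals: int = 10_000
    seed: int = 0
    represented_population: float = 147_852_423.0
    #: target mean SSB kcal/day per income tertile (low, middle, high)
    tertile_mean_kcal: tuple[float, float, float] = (53.5, 74.0, 86.7)
    #: multiplicative sex/age intake patterns (None -> published pattern)
    sex_multiplier: dict[str, float] | None = None
    age_multiplier: dict[str, float] | None = None
    #: population composition
    sex_share: dict[str, float] = field(
        default_factory=lambda: {"female": 0.529, "male": 0.471}
    )
    age_share: dict[str, float] = field(
        default_factory=lambda: {"20-39": 0.421, "40-59": 0.364, "60+": 0.215}
    )
    #: day-level zero-consumption probability and gamma shape of SSB intake
    zero_intake_prob: float = 0.5
    intake_gamma_shape: float = 0.8
    #: mean kcal/day of the non-taxed beverages (not published; realistic picks)
    other_beverage_kcal: dict[str, float] = field(
        default_factory=lambda: {"unsweetened": 55.0, "alcoholic": 45.0, "diet": 1.0}
    )
    other_zero_prob: dict[str, float] = field(
        default_factory=lambda: {"unsweetened": 0.3, "alcoholic": 0.75, "diet": 0.9}
    )
    #: true BMI ~ lognormal by sex, calibrated to ~25.2% adult obesity
    bmi_log_mean: dict[str, float] = field(
        default_factory=lambda: {"female": math.log(27.2), "male": math.log(26.0)}
    )
    bmi_log_sd: dict[str, float] = field(
        default_factory=lambda: {"female": 0.185, "male": 0.170}
    )
    height_mean: dict[str, float] = field(
        default_factory=lambda: {"female": 1.585, "male": 1.715}
    )
    height_sd: dict[str, float] = field(
        default_factory=lambda: {"female": 0.065, "male": 0.070}
    )
    bias: BiasModel = field(default_factory=BiasModel)

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals", "must be >= 1")
        if any(m < 0 for m in self.tertile_mean_kcal):
            raise ConfigurationError("tertile_mean_kcal", "means must be >= 0")
        if any(v < 0 for v in self.other_beverage_kcal.values()):
            raise ConfigurationError("other_beverage_kcal", "means must be >= 0")
        if not 0.0 <= self.zero_intake_prob < 1.0:
            raise ConfigurationError("zero_intake_prob", "must be in [0, 1)")
        if self.represented_population <= 0:
            raise ConfigurationError("represented_population", "must be > 0")


def generate_individuals(cfg: IndividualConfig) -> pd.DataFrame:
    """Generate adults with beverage intake and (true + self-reported) anthropometry.

    Group mean SSB kcal/day equals the configured tertile target times the
    sex/age multipliers (normalised so tertile means are honoured exactly in
    expectation); intake is zero-inflated gamma, hence right-skewed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals

    sex_mult, age_mult = _sex_age_tertile_multipliers()
    if cfg.sex_multiplier is not None:
        sex_mult = cfg.sex_multiplier
    if cfg.age_multiplier is not None:
        age_mult = cfg.age_multiplier
    # normalise so the composition-weighted multiplier is 1 within a tertile
    s_norm = sum(cfg.sex_share[s] * sex_mult[s] for s in SEXES)
    a_norm = sum(cfg.age_share[a] * age_mult[a] for a in AGE_GROUPS)

    sex = rng.choice(SEXES, n, p=[cfg.sex_share[s] for s in SEXES])
    ageband = rng.choice(AGE_GROUPS, n, p=[cfg.age_share[a] for a in AGE_GROUPS])
    age_low = np.select([ageband == "20-39", ageband == "40-59"], [20, 40], 60)
    age_span = np.select([ageband == "20-39", ageband == "40-59"], [20, 20], 20)
    age = age_low + rng.random(n) * age_span

    weights = rng.gamma(5.0, 1.0, n)
    weights = weights * (cfg.represented_population / weights.sum())
    tertile = weighted_tertiles(rng.lognormal(0.2, 0.8, n), weights)

    tert_target = np.asarray(cfg.tertile_mean_kcal)
    smul = np.array([sex_mult[s] for s in sex]) / s_norm
    amul = np.array([age_mult[a] for a in ageband]) / a_norm
    mean_kcal = tert_target[tertile - 1] * smul * amul

    dens = beverage_tables()["kcal_per_ml"]
    k = cfg.intake_gamma_shape
    drinkers = rng.random(n) >= cfg.zero_intake_prob
    cond_mean = mean_kcal / (1.0 - cfg.zero_intake_prob)
    kcal_ssb = np.where(drinkers, rng.gamma(k, 1.0, n) * cond_mean / k, 0.0)

    data = {
        "person_id": np.arange(n),
        "sex": sex,
        "age": age,
        "age_group": ageband,
        "income_tertile": tertile,
        "survey_weight": weights,
        "kcal_ssb": kcal_ssb,
        "ml_ssb": kcal_ssb / dens["ssb"],
    }

    for cat, mu in cfg.other_beverage_kcal.items():
        p0 = cfg.other_zero_prob.get(cat, 0.0)
        on = rng.random(n) >= p0
        kcal = np.where(on, rng.gamma(k, 1.0, n) * (mu / (1 - p0)) / k, 0.0)
        data[f"kcal_{cat}"] = kcal
        data[f"ml_{cat}"] = kcal / max(dens[cat], 1e-9)

    height = np.empty(n)
    bmi = np.empty(n)
    for s in SEXES:
        m = sex == s
        height[m] = rng.normal(cfg.height_mean[s], cfg.height_sd[s], m.sum())
        bmi[m] = rng.lognormal(cfg.bmi_log_mean[s], cfg.bmi_log_sd[s], m.sum())
    height = np.clip(height, 1.35, 2.10)
    weight = bmi * height**2

    w_int = np.array([cfg.bias.weight_intercept[s] for s in sex])
    w_slope = np.array([cfg.bias.weight_slope[s] for s in sex])
    h_shift = np.array([cfg.bias.height_shift[s] for s in sex])
    data.update(
        height_true=height,
        weight_true=weight,
        weight_self=weight - (w_int + w_slope * (weight - 60.0)),
        height_self=height + h_shift,
    )
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# population projection
# ---------------------------------------------------------------------------


def generate_projection(
    start: float, years: range, growth: float = 0.012
) -> pd.DataFrame:
    """Yearly adult population: `start` persons in `years[0]`, compounding at `growth`/yr.

    Stand-in for official demographic projections, which are not shipped.
    """
    if start <= 0:
        raise ConfigurationError("start", "population must be > 0")
    if len(years) == 0:
        raise ConfigurationError("years", "year range is empty")
    k = np.arange(len(years))
    return pd.DataFrame({"year": list(years), "adults": start * (1.0 + growth) ** k})
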