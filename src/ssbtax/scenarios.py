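"""Caloric-change scenarios under an ad valorem SSB tax.

A tax of rate ``r`` with pass-through ``phi`` raises the SSB price by
``r * phi``; with constant elasticity and the linearity assumption for
moderate price changes, the daily caloric change of a person with baseline
SSB intake ``k`` and tertile elasticity ``e`` is ``k * r * phi * e``.
Substitution adds, per non-taxed beverage category, baseline kcal times
rate times the category's cross elasticity with respect to the SSB price
(negative net cross effects mean substitution *adds* a small caloric
reduction, as estimated for Brazil, where alcohol is a complement).
Post-tax intake of each category is truncated at zero kcal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import TAXED_CATEGORY, TERTILES
from .errors import ValidationError
from .intake import stratified_means, national_mean
from .reference import reference_elasticity_table


@dataclass(frozen=True)
class TaxScenario:
    """An ad valorem SSB tax scenario."""

    rate: float  # e.g. 0.20 or 0.30
    pass_through: float = 1.0
    include_substitution: bool = False

    def __post_init__(self):
        if self.rate < 0:
            raise ValidationError(f"tax rate must be >= 0, got {self.rate}")
        if not 0.0 < self.pass_through <= 1.5:
            raise ValidationError(f"pass-through must be in (0, 1.5], got {self.pass_through}")

    @property
    def price_change(self) -> float:
        return self.rate * self.pass_through


def ssb_caloric_change(baseline_kcal, own_elasticity, scenario: TaxScenario):
    """Daily kcal change from the taxed category itself.

    Truncated so post-tax intake is never negative.
    """
    k = np.asarray(baseline_kcal, dtype=float)
    if np.any(k < 0):
        raise ValidationError("baseline kcal must be >= 0")
    delta = k * scenario.price_change * np.asarray(own_elasticity, dtype=float)
    return np.maximum(delta, -k)


def substitution_caloric_change(
    baseline_kcal_by_category: dict[str, np.ndarray | float],
    cross_elasticities: dict[str, np.ndarray | float],
    scenario: TaxScenario,
):
    """Summed daily kcal change of the non-taxed beverages.

    `baseline_kcal_by_category` and `cross_elasticities` must cover the same
    categories; each category contributes baseline * rate * pass_through *
    cross elasticity, truncated at minus its baseline.
    """
    if set(baseline_kcal_by_category) != set(cross_elasticities):
        raise ValidationError(
            "category mismatch between baselines "
            f"{sorted(baseline_kcal_by_category)} and elasticities {sorted(cross_elasticities)}"
        )
    total = 0.0
    for cat, base in baseline_kcal_by_category.items():
        b = np.asarray(base, dtype=float)
        if np.any(b < 0):
            raise ValidationError(f"baseline kcal for '{cat}' must be >= 0")
        d = b * scenario.price_change * np.asarray(cross_elasticities[cat], dtype=float)
        total = total + np.maximum(d, -b)
    return total


def _elasticity_lookup(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """category -> array of elasticities indexed by tertile-1."""
    out = {}
    for cat, g in table.groupby("category"):
        arr = np.full(3, np.nan)
        for _, row in g.iterrows():
            arr[int(row["tertile"]) - 1] = row["elasticity"]
        out[cat] = arr
    return out


def individual_caloric_changes(
    individuals: pd.DataFrame,
    elasticity_table: pd.DataFrame,
    scenario: TaxScenario,
) -> pd.DataFrame:
    """Per-person Δkcal/day columns: `delta_ssb`, `delta_other`, `delta_total`."""
    look = _elasticity_lookup(elasticity_table)
    tert = individuals["income_tertile"].to_numpy(int)
    own = look[TAXED_CATEGORY][tert - 1]
    d_ssb = ssb_caloric_change(individuals["kcal_ssb"].to_numpy(), own, scenario)
    d_other = np.zeros(len(individuals))
    if scenario.include_substitution:
        bases, crosses = {}, {}
        for cat, e in look.items():
            if cat == TAXED_CATEGORY or f"kcal_{cat}" not in individuals:
                continue
            bases[cat] = individuals[f"kcal_{cat}"].to_numpy()
            crosses[cat] = e[tert - 1]
        if bases:
            d_other = substitution_caloric_change(bases, crosses, scenario)
    out = individuals[["person_id"]].copy()
    out["delta_ssb"] = d_ssb
    out["delta_other"] = d_other
    out["delta_total"] = d_ssb + d_other
    return out


def population_caloric_table(
    individuals: pd.DataFrame,
    elasticity_table: pd.DataFrame,
    scenario: TaxScenario,
    strata=("income_tertile",),
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified weighted mean caloric changes with bootstrap CIs."""
    deltas = individual_caloric_changes(individuals, elasticity_table, scenario)
    df = individuals.copy()
    for col in ("delta_ssb", "delta_other", "delta_total"):
        df[col] = deltas[col].to_numpy()
    tab = stratified_means(df, "delta_ssb", strata, n_boot=n_boot, seed=seed)
    tab = tab.rename(
        columns={"mean": "delta_ssb", "ci_low": "delta_ssb_lo", "ci_high": "delta_ssb_hi"}
    )
    other = stratified_means(df, "delta_other", strata, n_boot=n_boot, seed=seed + 1)
    tab["delta_other"] = other["mean"].to_numpy()
    tab["delta_total"] = tab["delta_ssb"] + tab["delta_other"]
    tab["national_delta_ssb"] = national_mean(df, "delta_ssb")
    tab["national_delta_total"] = national_mean(df, "delta_total")
    return tab


def reference_caloric_table(
    scenario: TaxScenario,
    baselines: pd.DataFrame | None = None,
    elasticity_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Arithmetic caloric-change table from the published group-level inputs.

    Applies the published per-tertile SSB elasticities to the published
    per-tertile baseline intakes; the national row is the
    population-weighted mean of the tertile cells.  No estimation involved.
    """
    from .reference import reference_tertile_baselines

    base = baselines if baselines is not None else reference_tertile_baselines()
    etab = elasticity_table if elasticity_table is not None else reference_elasticity_table()
    own = _elasticity_lookup(etab)[TAXED_CATEGORY]
    rows = []
    for _, r in base.iterrows():
        t = int(r["tertile"])
        delta = float(ssb_caloric_change(r["kcal_day"], own[t - 1], scenario))
        rows.append(
            {
                "tertile": t,
                "population_m": r["population_m"],
                "baseline_kcal": r["kcal_day"],
                "delta_kcal": delta,
            }
        )
    tab = pd.DataFrame(rows)
    tab["national_delta_kcal"] = float(
        np.average(tab["delta_kcal"], weights=tab["population_m"])
    )
    return tab
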