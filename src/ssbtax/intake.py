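"""Baseline beverage intake from 24-h recall records.

Single-recall intakes are taken at face value (no usual-intake
deconvolution).  Servings convert linearly to ml via the packaged serving
table, ml to kcal via the caloric-density table; stratified survey-weighted
means carry percentile confidence intervals from a seeded stratified
bootstrap over individuals.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .reference import beverage_tables


def servings_to_ml(servings, category: str, serving_table: dict | None = None):
    """Convert daily servings of a beverage category to ml/day."""
    table = serving_table or beverage_tables()["serving_ml"]
    if category not in table:
        raise ValidationError(f"unknown beverage category '{category}'")
    s = np.asarray(servings, dtype=float)
    if np.any(s < 0):
        raise ValidationError("servings must be >= 0")
    return s * table[category]


def ml_to_kcal(ml, category: str, density_table: dict | None = None):
    """Convert ml/day to kcal/day with the category caloric density."""
    table = density_table or beverage_tables()["kcal_per_ml"]
    if category not in table:
        raise ValidationError(f"unknown beverage category '{category}'")
    return np.asarray(ml, dtype=float) * table[category]


def weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    if np.any(weights <= 0):
        raise ValidationError("survey weights must be positive")
    return float(np.sum(weights * values) / np.sum(weights))


def stratified_means(
    individuals: pd.DataFrame,
    value: str,
    strata: Sequence[str] = ("income_tertile",),
    weight: str = "survey_weight",
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Survey-weighted mean of `value` per stratum with bootstrap CIs.

    Each bootstrap replicate resamples individuals with replacement within
    the stratum, keeping their weights.  Empty strata never appear (groupby
    drops them); a stratum present in the data is never reported as zero.
    """
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2
    rows = []
    grouped = individuals.groupby(list(strata), observed=True)
    for key, g in grouped:
        v = g[value].to_numpy(float)
        w = g[weight].to_numpy(float)
        est = weighted_mean(v, w)
        idx = rng.integers(0, len(g), size=(n_boot, len(g)))
        boots = (w[idx] * v[idx]).sum(axis=1) / w[idx].sum(axis=1)
        lo, hi = np.quantile(boots, [alpha, 1 - alpha])
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(strata, key))
            | {
                "mean": est,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n": len(g),
                "population": float(w.sum()),
            }
        )
    return pd.DataFrame(rows)


def national_mean(individuals: pd.DataFrame, value: str, weight: str = "survey_weight") -> float:
    """Population-weighted national mean (equals the population-share-weighted
    mean of stratum means for any partition of the sample)."""
    return weighted_mean(individuals[value].to_numpy(), individuals[weight].to_numpy())
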