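"""Packaged reference inputs: published Brazilian estimates and model constants.

Three YAML files ship with the package:

``brazil_2018.yaml``
    Published beverage price elasticities by income tertile, baseline SSB
    caloric intake by stratum with represented populations, obesity
    prevalence, and obesity cost figures for Brazil.  Used by the
    paper-constants pipeline mode, and as defaults for the synthetic
    generator's study conditions.
``hall_parameters.yaml``
    Constants of the Hall adult energy-balance ODE model (annotated with
    units and provenance).
``beverage_tables.yaml``
    Serving-size (ml) and caloric-density (kcal/ml) tables per beverage
    category.
"""

from __future__ import annotations

import functools
from importlib import resources

import pandas as pd
import yaml

from .categories import BEVERAGE_CATEGORIES, TERTILE_LABELS


def _load_yaml(name: str) -> dict:
    with resources.files("ssbtax.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


@functools.cache
def brazil_reference() -> dict:
    """The published Brazilian input figures as a nested dict."""
    return _load_yaml("brazil_2018.yaml")


@functools.cache
def hall_constants() -> dict:
    """Hall-model constants (flat dict plus `rmr` and `fat_init` sub-dicts)."""
    return _load_yaml("hall_parameters.yaml")


@functools.cache
def beverage_tables() -> dict:
    """Serving-size and caloric-density tables keyed by beverage category."""
    return _load_yaml("beverage_tables.yaml")


def reference_elasticity_table() -> pd.DataFrame:
    """Published elasticity table as a tidy DataFrame.

    Columns: category, tertile (1..3), elasticity, se, p_value,
    n_observations.  Elasticities are with respect to the SSB price (own
    for the ssb row, cross otherwise).
    """
    ref = brazil_reference()["elasticities"]
    rows = []
    for cat in BEVERAGE_CATEGORIES:
        entry = ref[cat]
        for i, tert in enumerate(sorted(TERTILE_LABELS)):
            rows.append(
                {
                    "category": cat,
                    "tertile": tert,
                    "elasticity": float(entry["value"][i]),
                    "se": float(entry["se"][i]),
                    "p_value": float(entry["p"][i]),
                    "n_observations": int(entry["n_observations"]),
                }
            )
    return pd.DataFrame(rows)


def reference_tertile_baselines() -> pd.DataFrame:
    """Baseline SSB kcal/day and population (millions) per income tertile."""
    ref = brazil_reference()["baseline_intake"]["by_tertile"]
    rows = [
        {
            "tertile": tert,
            "label": label,
            "population_m": float(ref[label]["population_m"]),
            "kcal_day": float(ref[label]["kcal_day"]),
        }
        for tert, label in sorted(TERTILE_LABELS.items())
    ]
    return pd.DataFrame(rows)
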