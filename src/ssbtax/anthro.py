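"""Quantile-mapping correction of self-reported weight and height.

Self-reported anthropometry is biased (weight under-reported, height
over-reported, more strongly in women).  With a measured reference survey
that cannot be linked at the individual level, the correction aligns
distributions: the bias at probability p is the difference between the
measured and self-reported sample quantiles, smoothed with a cubic spline
over a grid of probabilities; each self-reported value is then shifted by
the spline evaluated at its own quantile.  Curves are fitted separately by
sex and variable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .errors import ValidationError
from .intake import weighted_mean

DEFAULT_GRID = np.linspace(0.01, 0.99, 99)
MIN_SAMPLE = 30


def weighted_quantile(values, probs, weights=None) -> np.ndarray:
    """Survey-weighted quantiles (linear interpolation on the weighted CDF)."""
    values = np.asarray(values, float)
    probs = np.atleast_1d(np.asarray(probs, float))
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(probs, cw, v)


@dataclass
class BiasCurve:
    """Smoothed quantile-difference bias for one sex and variable."""

    sex: str
    variable: str  # "weight" or "height"
    grid: np.ndarray
    bias_at_quantile: np.ndarray
    self_quantiles: np.ndarray  # self-reported quantile function on the grid
    smoothing_lam: float | None = None  # None -> generalized cross-validation
    _spline: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        g = np.asarray(self.grid, float)
        if np.any(np.diff(g) <= 0) or g[0] <= 0 or g[-1] >= 1:
            raise ValidationError("quantile grid must be strictly increasing within (0, 1)")
        if self._spline is None:
            self._spline = make_smoothing_spline(
                g, np.asarray(self.bias_at_quantile, float), lam=self.smoothing_lam
            )

    def bias(self, p) -> np.ndarray:
        """Spline bias at probability p, flat beyond the grid ends."""
        p = np.clip(np.asarray(p, float), self.grid[0], self.grid[-1])
        return self._spline(p)

    def quantile_of(self, values) -> np.ndarray:
        """Probability position of `values` in the self-reported distribution."""
        return np.interp(
            np.asarray(values, float),
            self.self_quantiles,
            self.grid,
            left=self.grid[0],
            right=self.grid[-1],
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "sex": self.sex,
                "variable": self.variable,
                "grid": self.grid.tolist(),
                "bias_at_quantile": np.asarray(self.bias_at_quantile, float).tolist(),
                "self_quantiles": np.asarray(self.self_quantiles, float).tolist(),
                "smoothing_lam": self.smoothing_lam,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "BiasCurve":
        d = json.loads(payload)
        return cls(
            sex=d["sex"],
            variable=d["variable"],
            grid=np.asarray(d["grid"]),
            bias_at_quantile=np.asarray(d["bias_at_quantile"]),
            self_quantiles=np.asarray(d["self_quantiles"]),
            smoothing_lam=d["smoothing_lam"],
        )


def fit_bias_curve(
    self_reported,
    measured,
    sex: str,
    variable: str,
    self_weights=None,
    measured_weights=None,
    grid: np.ndarray = DEFAULT_GRID,
    smoothing_lam: float | None = None,
) -> BiasCurve:
    """Fit the quantile-difference bias curve for one sex and variable.

    bias(p) = Q_measured(p) - Q_self(p) on the grid, smoothed by a cubic
    spline (lambda by generalized cross-validation unless given).
    """
    self_reported = np.asarray(self_reported, float)
    measured = np.asarray(measured, float)
    if len(self_reported) < MIN_SAMPLE or len(measured) < MIN_SAMPLE:
        raise ValidationError(
            f"need at least {MIN_SAMPLE} observations per sample for sex='{sex}', "
            f"variable='{variable}' (got {len(self_reported)} self-reported, "
            f"{len(measured)} measured)"
        )
    q_self = weighted_quantile(self_reported, grid, self_weights)
    q_meas = weighted_quantile(measured, grid, measured_weights)
    return BiasCurve(
        sex=sex,
        variable=variable,
        grid=np.asarray(grid, float),
        bias_at_quantile=q_meas - q_self,
        self_quantiles=q_self,
        smoothing_lam=smoothing_lam,
    )


def apply_bias_correction(values, curve: BiasCurve) -> np.ndarray:
    """Corrected values: value + bias at the value's self-reported quantile."""
    values = np.asarray(values, float)
    return values + curve.bias(curve.quantile_of(values))


def correct_cohort(
    individuals: pd.DataFrame,
    reference: pd.DataFrame,
    weight_col: str = "weight_self",
    height_col: str = "height_self",
    ref_weight_col: str = "weight_true",
    ref_height_col: str = "height_true",
    smoothing_lam: float | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], BiasCurve]]:
    """Correct a cohort's self-reported anthropometry against a measured survey.

    Fits sex-specific weight and height bias curves between the cohort's
    self-reports and the reference's measured values (both survey-weighted)
    and adds `weight_corrected` / `height_corrected` columns.
    """
    out = individuals.copy()
    out["weight_corrected"] = np.nan
    out["height_corrected"] = np.nan
    curves: dict[tuple[str, str], BiasCurve] = {}
    for sex in individuals["sex"].unique():
        m = individuals["sex"] == sex
        mr = reference["sex"] == sex
        for var, col, refcol in (
            ("weight", weight_col, ref_weight_col),
            ("height", height_col, ref_height_col),
        ):
            curve = fit_bias_curve(
                individuals.loc[m, col],
                reference.loc[mr, refcol],
                sex,
                var,
                self_weights=individuals.loc[m, "survey_weight"],
                measured_weights=reference.loc[mr, "survey_weight"],
                smoothing_lam=smoothing_lam,
            )
            curves[(sex, var)] = curve
            out.loc[m, f"{var}_corrected"] = apply_bias_correction(
                individuals.loc[m, col], curve
            )
    return out, curves


def bmi(weight, height) -> np.ndarray:
    """Body mass index kg/m^2."""
    h = np.asarray(height, float)
    if np.any(h <= 0):
        raise ValidationError("height must be positive")
    return np.asarray(weight, float) / h**2


def obesity_prevalence(
    individuals: pd.DataFrame,
    use_corrected: bool = True,
    threshold: float = 30.0,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Survey-weighted obesity prevalence (BMI >= 30) with a bootstrap CI."""
    suffix = "corrected" if use_corrected else "self"
    b = bmi(individuals[f"weight_{suffix}"], individuals[f"height_{suffix}"])
    w = individuals["survey_weight"].to_numpy(float)
    obese = (b >= threshold).astype(float)
    est = weighted_mean(obese, w)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(obese), size=(n_boot, len(obese)))
    boots = (w[idx] * obese[idx]).sum(axis=1) / w[idx].sum(axis=1)
    lo, hi = np.quantile(boots, [0.025, 0.975])
    return {"prevalence": est, "ci_low": float(lo), "ci_high": float(hi)}
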