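"""Obesity outcomes: prevalence trajectories, cases averted, uncertainty.

Baseline prevalence is held at its year-0 value over the whole horizon
(steady-state assumption); the scenario prevalence is the survey-weighted
share of simulated BMI >= 30 at each 365-day mark.  Cases averted multiply
the absolute prevalence reduction by the projected adult population of the
same year.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .hall import DAYS_PER_YEAR, Trajectory


def prevalence_series(
    trajectory: Trajectory,
    survey_weights: np.ndarray,
    horizon_years: int = 10,
    threshold: float = 30.0,
) -> pd.DataFrame:
    """Yearly obesity prevalence under the scenario vs the fixed baseline.

    Columns: year (1..horizon), baseline, scenario, absolute_change (pp as
    fraction, scenario - baseline), relative_change (absolute / baseline).
    """
    w = np.asarray(survey_weights, float)
    if len(w) != trajectory.weight.shape[0]:
        raise ValidationError("survey weights do not match the cohort size")
    if np.any(w <= 0):
        raise ValidationError("survey weights must be positive")
    bmi = trajectory.bmi
    day_index = {int(d): j for j, d in enumerate(trajectory.days)}
    try:
        cols = [day_index[y * DAYS_PER_YEAR] for y in range(0, horizon_years + 1)]
    except KeyError as exc:
        raise ValidationError(f"trajectory does not cover day {exc} of the horizon")
    prev = [(w * (bmi[:, j] >= threshold)).sum() / w.sum() for j in cols]
    baseline = prev[0]
    rows = []
    for y in range(1, horizon_years + 1):
        absolute = prev[y] - baseline
        rows.append(
            {
                "year": y,
                "baseline": baseline,
                "scenario": prev[y],
                "absolute_change": absolute,
                "relative_change": absolute / baseline if baseline > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def cases_averted(series: pd.DataFrame, projection: pd.DataFrame) -> pd.DataFrame:
    """Yearly and cumulative obesity cases averted against a projection.

    The projection supplies the adult population for each of the horizon's
    calendar years, in order; cases_y = -absolute_change_y x adults_y.
    """
    if len(projection) < len(series):
        raise ValidationError(
            f"projection covers {len(projection)} years, series needs {len(series)}"
        )
    adults = projection["adults"].to_numpy(float)[: len(series)]
    out = series.copy()
    out["adults"] = adults
    out["cases_averted"] = -out["absolute_change"].to_numpy() * adults
    out["cumulative_cases_averted"] = out["cases_averted"].cumsum()
    return out


def bootstrap_uncertainty(
    trajectory: Trajectory,
    survey_weights: np.ndarray,
    statistic,
    n_reps: int = 200,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Percentile CI for a cohort statistic by resampling individuals.

    Because every downstream stage is deterministic per individual,
    resampling persons (with their weights and simulated trajectories) is
    identical to re-running the scenario/weight stages per replicate.
    `statistic(trajectory, weights)` must return a float.
    """
    if n_reps < 100:
        raise ValidationError("n_reps must be >= 100")
    w = np.asarray(survey_weights, float)
    n = trajectory.weight.shape[0]
    rng = np.random.default_rng(seed)
    est = float(statistic(trajectory, w))
    reps = np.empty(n_reps)
    for r in range(n_reps):
        idx = rng.integers(0, n, n)
        sub = Trajectory(
            days=trajectory.days,
            weight=trajectory.weight[idx],
            height=trajectory.height[idx],
        )
        reps[r] = statistic(sub, w[idx])
    alpha = (1 - ci_level) / 2
    lo, hi = np.quantile(reps, [alpha, 1 - alpha])
    return {"estimate": est, "ci_low": float(lo), "ci_high": float(hi), "reps": reps}
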