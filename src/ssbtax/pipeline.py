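"""End-to-end orchestration of the tax-simulation pipeline.

One config drives: synthetic cohort generation (or paper-constants mode,
which skips estimation and uses the packaged published inputs), demand
estimation, anthropometric correction, the {20%, 30%} x {SSB-only, with
substitution} scenario grid, the dynamic weight simulation, obesity
outcomes against a population projection, and discounted cost savings.
Every stage seed derives from the single global seed; a manifest records
the config hash so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anthro, costs, demand, hall, outcomes, scenarios, synthetic
from .errors import SSBTaxError
from .reference import reference_elasticity_table


@dataclass
class PipelineConfig:
    seed: int = 0
    n_individuals: int = 5000
    n_households: int = 20000
    #: estimate elasticities from synthetic households; else use the
    #: packaged published table (paper-constants mode)
    estimate_elasticities: bool = False
    tax_rates: tuple[float, ...] = (0.20, 0.30)
    substitution_options: tuple[bool, ...] = (False, True)
    horizon_years: int = 10
    projection_start: float = 147.9e6
    projection_growth: float = 0.012
    projection_start_year: int = 2021
    pal: float = 1.5
    output_dir: str | None = None
    household_config: synthetic.HouseholdConfig | None = None
    individual_config: synthetic.IndividualConfig | None = None

    def scenario_grid(self) -> list[scenarios.TaxScenario]:
        return [
            scenarios.TaxScenario(rate=r, include_substitution=s)
            for r in self.tax_rates
            for s in self.substitution_options
        ]


def _scenario_key(sc: scenarios.TaxScenario) -> str:
    return f"{int(round(sc.rate * 100))}pct_{'subs' if sc.include_substitution else 'ssb'}"


def _config_hash(cfg: PipelineConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(str(type(o)))

    payload = json.dumps(dataclasses.asdict(cfg), default=enc, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the result bundle (and writes artifacts if
    an output directory is configured)."""
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    bundle: dict = {"manifest": {"seed": cfg.seed, "config_hash": _config_hash(cfg)}}

    try:
        # --- demand stage -------------------------------------------------
        if cfg.estimate_elasticities:
            hcfg = cfg.household_config or synthetic.HouseholdConfig(
                n_households=cfg.n_households
            )
            hcfg = dataclasses.replace(hcfg, seed=seeds[0])
            households = synthetic.generate_households(hcfg)
            elasticities = demand.elasticity_matrix(households)
        else:
            elasticities = reference_elasticity_table()
        bundle["elasticities"] = elasticities

        # --- cohort + anthropometric correction ---------------------------
        icfg = cfg.individual_config or synthetic.IndividualConfig(
            n_individuals=cfg.n_individuals
        )
        icfg = dataclasses.replace(icfg, seed=seeds[1])
        cohort = synthetic.generate_individuals(icfg)
        # measured reference survey: an independent draw of the same
        # population, of which only the measured (true) anthropometry is used
        ref_cfg = dataclasses.replace(icfg, seed=seeds[2])
        reference_survey = synthetic.generate_individuals(ref_cfg)
        cohort, curves = anthro.correct_cohort(cohort, reference_survey)
        bundle["bias_curves"] = curves
        bundle["obesity_baseline"] = anthro.obesity_prevalence(
            cohort, use_corrected=True, seed=seeds[3]
        )

        # --- projection ----------------------------------------------------
        years = range(
            cfg.projection_start_year, cfg.projection_start_year + cfg.horizon_years
        )
        projection = synthetic.generate_projection(
            cfg.projection_start, years, cfg.projection_growth
        )
        bundle["projection"] = projection

        # --- scenario grid ------------------------------------------------
        state = hall.initialize_state(
            cohort["sex"].to_numpy(),
            cohort["age"].to_numpy(),
            cohort["weight_corrected"].to_numpy(),
            cohort["height_corrected"].to_numpy(),
            cfg.pal,
        )
        yearly = np.arange(0, cfg.horizon_years + 1) * hall.DAYS_PER_YEAR
        w = cohort["survey_weight"].to_numpy()
        cost_params = costs.CostParameters.brazil_default()

        bundle["caloric_tables"] = {}
        bundle["prevalence"] = {}
        bundle["cases"] = {}
        bundle["costs"] = {}
        bundle["weight_changes"] = {}
        for sc in cfg.scenario_grid():
            key = _scenario_key(sc)
            deltas = scenarios.individual_caloric_changes(cohort, elasticities, sc)
            bundle["caloric_tables"][key] = scenarios.population_caloric_table(
                cohort, elasticities, sc, n_boot=200, seed=seeds[4]
            )
            traj = hall.simulate_population(
                state,
                deltas["delta_total"].to_numpy(),
                horizon_days=cfg.horizon_years * hall.DAYS_PER_YEAR,
                output_days=yearly,
            )
            change = traj.weight_change()
            sexarr = cohort["sex"].to_numpy()
            bundle["weight_changes"][key] = {
                "mean": float(np.average(change, weights=w)),
                "female": float(np.average(change[sexarr == "female"], weights=w[sexarr == "female"])),
                "male": float(np.average(change[sexarr == "male"], weights=w[sexarr == "male"])),
            }
            series = outcomes.prevalence_series(traj, w, cfg.horizon_years)
            bundle["prevalence"][key] = series
            cases = outcomes.cases_averted(series, projection)
            bundle["cases"][key] = cases
            bundle["costs"][key] = costs.savings_split(
                cases["cases_averted"].to_numpy(), cost_params
            )
    except SSBTaxError as exc:
        raise SSBTaxError(f"pipeline failed: {exc}") from exc

    if cfg.output_dir is not None:
        _write_bundle(bundle, Path(cfg.output_dir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["elasticities"].to_csv(outdir / "elasticities.csv", index=False)
    bundle["projection"].to_csv(outdir / "projection.csv", index=False)
    for key, df in bundle["caloric_tables"].items():
        df.to_csv(outdir / f"caloric_{key}.csv", index=False)
    for key, df in bundle["prevalence"].items():
        df.to_csv(outdir / f"prevalence_{key}.csv", index=False)
    for key, df in bundle["cases"].items():
        df.to_csv(outdir / f"cases_{key}.csv", index=False)
    summary = {
        "weight_changes": bundle["weight_changes"],
        "obesity_baseline": bundle["obesity_baseline"],
        "costs": {
            k: {kk: vv for kk, vv in v.items() if kk != "ledger"}
            for k, v in bundle["costs"].items()
        },
        "manifest": bundle["manifest"],
    }
    for key, v in bundle["costs"].items():
        v["ledger"].to_csv(outdir / f"cost_ledger_{key}.csv", index=False)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
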