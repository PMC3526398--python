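"""End-to-end orchestration: simulate → episodes → measures → adjust → compare.

All randomness flows from the single run seed; outputs are plain CSV/JSON; a
JSON run report reconciles record counts at every stage boundary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from hospmort import episode_builder, mortality_measures, risk_adjustment
from hospmort.episode_builder import build_episodes
from hospmort.measure_comparison import compare_measures
from hospmort.mortality_measures import (
    compute_measure,
    crude_mortality,
    mean_los_by_hospital,
    summarize_cohort,
)
from hospmort.risk_adjustment import ModelSpec, adjust_measure, effects_to_frame
from hospmort.synthetic_registry import (
    SimulationConfig,
    default_config,
    generate_cohort,
    generate_hospitals,
    hospitals_to_frame,
    read_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)

MEASURES = ("W30D", "S30D", "IH30D")
COMPARISONS = (("W30D", "S30D"), ("W30D", "IH30D"))


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    If ``input_dir`` is None, a cohort is simulated from ``simulation`` (a
    SimulationConfig or a dict of overrides applied to the condition default).
    """

    condition: str = "AMI"
    out_dir: str = "results/run"
    input_dir: str | None = None
    simulation: SimulationConfig | dict | None = None
    seed: int | None = None
    window_days: int = 30
    max_gap_hours: float = 24.0
    min_volume: int = 20
    model: ModelSpec | dict = field(default_factory=ModelSpec)
    log_level: str = "info"

    def resolved_simulation(self) -> SimulationConfig:
        sim = self.simulation
        if isinstance(sim, SimulationConfig):
            cfg = sim
        else:
            cfg = default_config(self.condition, **(sim or {}))
        if self.seed is not None:
            cfg = dataclasses.replace(cfg, seed=self.seed)
        cfg.validate()
        return cfg

    def resolved_model(self) -> ModelSpec:
        if isinstance(self.model, ModelSpec):
            return self.model
        m = dict(self.model or {})
        if "age_knots" in m and m["age_knots"] is not None:
            m["age_knots"] = tuple(m["age_knots"])
        return ModelSpec(**m)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown run-config field(s): {sorted(unknown)}")
        return cls(**data)


def _set_log_level(level: str) -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run report."""
    _set_log_level(config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"condition": config.condition, "stages": {}}

    # --- input: simulate or load ------------------------------------------
    categories: dict | None = None
    if config.input_dir is None:
        sim = config.resolved_simulation()
        hospitals = generate_hospitals(sim)
        admissions, vitals, truth = generate_cohort(sim, hospitals)
        write_cohort(out, admissions, vitals, truth, hospitals)
        categories = {h.hospital_id: h.category for h in hospitals}
        report["stages"]["simulate"] = {
            "n_hospitals": len(hospitals),
            "n_admission_records": int(len(admissions)),
            "n_deaths": int(len(vitals)),
        }
    else:
        admissions, vitals = read_cohort(config.input_dir)
        hosp_file = Path(config.input_dir) / "hospitals.csv"
        if hosp_file.exists():
            hf = pd.read_csv(hosp_file)
            categories = dict(zip(hf["hospital_id"], hf["category"]))
        report["stages"]["load"] = {
            "n_admission_records": int(len(admissions)),
            "n_deaths": int(len(vitals)),
        }

    # --- exclusions and volume filter --------------------------------------
    retained, log = episode_builder.apply_exclusions(
        admissions, config.condition, config.max_gap_hours
    )
    retained, dropped_hospitals = episode_builder.filter_hospitals_by_volume(
        retained, config.min_volume, years=episode_builder.study_years(retained)
    )
    if retained.empty or retained["hospital_id"].nunique() < 2:
        raise PipelineError("no hospitals retained after the volume filter")
    log.loc[
        log["retained"]
        & admissions["hospital_id"].isin(dropped_hospitals).reindex(log.index, fill_value=False),
        ["retained", "reason"],
    ] = [False, "low_volume_hospital"]
    log.to_csv(out / "exclusions.csv", index=False)
    report["stages"]["exclusions"] = {
        "n_input": int(len(admissions)),
        "n_retained": int(len(retained)),
        "n_excluded": int((~log["retained"]).sum()),
        "by_reason": log.loc[~log["retained"], "reason"].value_counts().to_dict(),
        "dropped_hospitals": dropped_hospitals,
    }

    # --- episodes -----------------------------------------------------------
    episodes = build_episodes(retained, vitals, config.max_gap_hours)
    episode_builder.write_episodes(out, episodes)
    summary = summarize_cohort(episodes, config.window_days)
    with open(out / "cohort_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    report["stages"]["episodes"] = {
        "n_episodes": len(episodes),
        "n_transferred": summary["n_transferred"],
        "n_stays": int(sum(len(e.stays) for e in episodes)),
    }

    # --- measures and adjustment -------------------------------------------
    spec = config.resolved_model()
    tables = {}
    crude = {}
    fits = {}
    effects = {}
    for m in MEASURES:
        tables[m] = compute_measure(m, episodes, config.window_days)
        crude_df, overall = crude_mortality(tables[m])
        crude[m] = (crude_df, overall)
        crude_df.to_csv(out / f"crude_{m}.csv", index=False, float_format="%.10g")
        fit, eff = adjust_measure(tables[m], spec)
        fits[m], effects[m] = fit, eff
        effects_to_frame(eff, fit.penalized).to_csv(
            out / f"effects_{m}.csv", index=False, float_format="%.10g"
        )
        with open(out / f"model_{m}.json", "w") as fh:
            json.dump(
                {
                    "measure": m,
                    "coefficients": fit.params.round(10).to_dict(),
                    "converged": fit.converged,
                    "penalized": fit.penalized,
                    "n_iterations": fit.n_iterations,
                    "log_likelihood": fit.log_likelihood,
                    "c_statistic": fit.c_statistic,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        report["stages"][f"measure_{m}"] = {
            "n_observations": len(tables[m]),
            "overall_crude_pct": round(100 * overall, 4),
            "c_statistic": fit.c_statistic,
            "penalized": fit.penalized,
        }
    mortality_measures.write_measure_tables(out, list(tables.values()))

    # --- comparisons ---------------------------------------------------------
    los = mean_los_by_hospital(episodes)
    report["comparisons"] = {}
    for ref, other in COMPARISONS:
        ranks_ref = {e.hospital_id: e.rank for e in effects[ref]}
        ranks_other = {e.hospital_id: e.rank for e in effects[other]}
        status_ref = {e.hospital_id: e.outlier for e in effects[ref]}
        status_other = {e.hospital_id: e.outlier for e in effects[other]}
        res = compare_measures(
            ranks_ref, ranks_other, status_ref, status_other, (ref, other),
            categories=categories, mean_los=los,
        )
        name = f"{other}_vs_{ref}"
        with open(out / f"comparison_{name}.json", "w") as fh:
            json.dump(res.to_dict(), fh, indent=2, sort_keys=True)
        res.outlier_crosstab.to_csv(out / f"crosstab_{name}.csv")
        report["comparisons"][f"adjusted_{name}"] = {
            "spearman_r": res.spearman_r,
            "change_fraction": res.change_fraction,
            "anova_p": res.anova_p,
            "fisher_p": res.fisher_p,
        }
        # unadjusted (crude-proportion) ranking comparison
        cr_ref = dict(
            zip(crude[ref][0]["hospital_id"], crude[ref][0]["crude_mortality"])
        )
        cr_other = dict(
            zip(crude[other][0]["hospital_id"], crude[other][0]["crude_mortality"])
        )
        common = set(cr_ref) & set(cr_other)
        ranks_u_ref = risk_adjustment.rank_hospitals({h: cr_ref[h] for h in common})
        ranks_u_other = risk_adjustment.rank_hospitals({h: cr_other[h] for h in common})
        res_u = compare_measures(
            ranks_u_ref, ranks_u_other, None, None, (ref, other)
        )
        report["comparisons"][f"unadjusted_{name}"] = {
            "spearman_r": res_u.spearman_r,
        }

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
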