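"""Reusable simulation studies over the full pipeline.

These routines drive simulate → episodes → measures → adjust → compare at
configurable scale; the analysis scripts and the acceptance checks call them
rather than re-scripting the stages.
"""

from __future__ import annotations

import numpy as np

from hospmort.episode_builder import (
    apply_exclusions,
    build_episodes,
    filter_hospitals_by_volume,
    study_years,
)
from hospmort.measure_comparison import compare_measures
from hospmort.mortality_measures import (
    compute_measure,
    crude_mortality,
    mean_los_by_hospital,
    summarize_cohort,
)
from hospmort.risk_adjustment import ModelSpec, adjust_measure
from hospmort.synthetic_registry import (
    default_config,
    generate_cohort,
    generate_hospitals,
)

MEASURES = ("W30D", "S30D", "IH30D")


def simulate_episodes(config, min_volume: int = 20):
    """Generate a cohort and run it through exclusions and chaining.

    Returns ``(hospitals, episodes, truth)``.
    """
    hospitals = generate_hospitals(config)
    admissions, vitals, truth = generate_cohort(config, hospitals)
    retained, _ = apply_exclusions(admissions, config.condition)
    retained, _ = filter_hospitals_by_volume(
        retained, min_volume, years=study_years(retained)
    )
    episodes = build_episodes(retained, vitals)
    return hospitals, episodes, truth


def null_outlier_calibration(
    n_replicates: int = 200,
    seed: int = 0,
    tail: float = 0.05,
    n_hospitals: dict | None = None,
    patients_per_hospital_year: dict | None = None,
) -> dict:
    """Outlier flag rates when every true hospital effect is zero.

    Simulates ``n_replicates`` one-year registries with
    ``hospital_effect_sd = 0``, fits the W30D adjustment model on each, and
    returns the mean per-tail (low / high) flag rates.  With a correctly
    calibrated Wald Z each tail should flag about ``tail`` of hospitals.
    """
    # volumes mirror the AMI defaults so per-hospital event counts are realistic
    n_hospitals = n_hospitals or {"small": 10, "large": 4, "university": 1}
    ppy = patients_per_hospital_year or {
        "small": 101.0,
        "large": 264.0,
        "university": 380.0,
    }
    rng = np.random.default_rng(seed)
    low_rates, high_rates = [], []
    for _ in range(n_replicates):
        cfg = default_config(
            "AMI",
            seed=int(rng.integers(0, 2**31 - 1)),
            years=1,
            hospital_effect_sd=0.0,
            n_hospitals=n_hospitals,
            patients_per_hospital_year=ppy,
        )
        _, episodes, _ = simulate_episodes(cfg)
        _, effects = adjust_measure(
            compute_measure("W30D", episodes), ModelSpec(tail=tail)
        )
        J = len(effects)
        low_rates.append(sum(e.outlier == "low" for e in effects) / J)
        high_rates.append(sum(e.outlier == "high" for e in effects) / J)
    return {
        "n_replicates": n_replicates,
        "mean_low_rate": float(np.mean(low_rates)),
        "mean_high_rate": float(np.mean(high_rates)),
    }


def parameter_recovery(
    seed: int = 0,
    hospital_effect_sd: float = 0.3,
    scale: float = 1.0,
    condition: str = "AMI",
) -> dict:
    """Correlation between true and estimated W30D hospital deviations.

    Uses the full 55-hospital roster; ``scale`` multiplies per-hospital
    volumes (scale 1 gives roughly 50 000 episodes over 5 years).
    """
    base = default_config(condition)
    ppy = {k: v * 1.05 * scale for k, v in base.patients_per_hospital_year.items()}
    cfg = default_config(
        condition,
        seed=seed,
        hospital_effect_sd=hospital_effect_sd,
        patients_per_hospital_year=ppy,
    )
    hospitals, episodes, _ = simulate_episodes(cfg)
    _, effects = adjust_measure(compute_measure("W30D", episodes), ModelSpec())
    true = {h.hospital_id: h.true_effect for h in hospitals}
    est = {e.hospital_id: e.beta for e in effects}
    ids = sorted(set(true) & set(est))
    t = np.array([true[i] for i in ids])
    b = np.array([est[i] for i in ids])
    return {
        "n_episodes": len(episodes),
        "n_hospitals": len(ids),
        "correlation": float(np.corrcoef(t, b)[0, 1]),
        "rmse": float(np.sqrt(((b - t) ** 2).mean())),
    }


def condition_study(condition: str, seed: int = 0, scale: float = 1.0) -> dict:
    """Full single-condition study: margins, adjusted profiles, comparisons.

    ``scale`` multiplies per-hospital volumes (1.0 reproduces the default
    full-size registry for the condition).
    """
    base = default_config(condition)
    cfg = default_config(
        condition,
        seed=seed,
        patients_per_hospital_year={
            k: v * scale for k, v in base.patients_per_hospital_year.items()
        },
    )
    hospitals, episodes, truth = simulate_episodes(cfg)
    summary = summarize_cohort(episodes)
    categories = {h.hospital_id: h.category for h in hospitals}
    los = mean_los_by_hospital(episodes)

    out: dict = {
        "condition": condition,
        "n_episodes": len(episodes),
        "summary": summary,
        "measures": {},
        "comparisons": {},
    }
    effects = {}
    for m in MEASURES:
        table = compute_measure(m, episodes)
        _, overall = crude_mortality(table)
        fit, eff = adjust_measure(table, ModelSpec())
        effects[m] = eff
        out["measures"][m] = {
            "n_observations": len(table),
            "overall_crude_pct": 100.0 * overall,
            "c_statistic": fit.c_statistic,
            "penalized": fit.penalized,
        }
    for other in ("S30D", "IH30D"):
        ranks_ref = {e.hospital_id: e.rank for e in effects["W30D"]}
        status_ref = {e.hospital_id: e.outlier for e in effects["W30D"]}
        common = set(ranks_ref) & {e.hospital_id for e in effects[other]}
        res = compare_measures(
            {h: r for h, r in ranks_ref.items() if h in common},
            {e.hospital_id: e.rank for e in effects[other] if e.hospital_id in common},
            {h: s for h, s in status_ref.items() if h in common},
            {e.hospital_id: e.outlier for e in effects[other] if e.hospital_id in common},
            ("W30D", other),
            categories={h: c for h, c in categories.items() if h in common},
            mean_los={h: v for h, v in los.items() if h in common},
        )
        out["comparisons"][f"{other}_vs_W30D"] = {
            "spearman_r": res.spearman_r,
            "change_fraction_pct": 100.0 * res.change_fraction,
            "correlation_with_los": res.correlation_with_los,
            "anova_p": res.anova_p,
            "fisher_p": res.fisher_p,
        }
    return out
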