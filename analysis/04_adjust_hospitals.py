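#!/usr/bin/env python
"""Fit the case-mix adjustment model per measure and profile hospitals.

Reads the measure tables from 03, writes deviation effects (beta, SE, Z,
outlier category, rank) and model summaries, and prints C-statistics and
outlier counts per condition and measure.
"""

import json
from pathlib import Path

import pandas as pd

from hospmort.mortality_measures import MeasureTable
from hospmort.risk_adjustment import ModelSpec, adjust_measure, effects_to_frame

ROOT = Path(__file__).resolve().parents[1] / "results"

for cond in ("AMI", "stroke", "hip_fracture"):
    out = ROOT / "effects" / cond
    out.mkdir(parents=True, exist_ok=True)
    line = [cond]
    for m in ("W30D", "S30D", "IH30D"):
        obs = pd.read_csv(ROOT / "measures" / cond / f"measure_{m}.csv")
        fit, effects = adjust_measure(MeasureTable(m, obs), ModelSpec())
        effects_to_frame(effects, fit.penalized).to_csv(
            out / f"effects_{m}.csv", index=False, float_format="%.10g"
        )
        with open(out / f"model_{m}.json", "w") as fh:
            json.dump(
                {
                    "measure": m,
                    "coefficients": fit.params.round(10).to_dict(),
                    "converged": fit.converged,
                    "penalized": fit.penalized,
                    "c_statistic": fit.c_statistic,
                    "log_likelihood": fit.log_likelihood,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        n_low = sum(e.outlier == "low" for e in effects)
        n_high = sum(e.outlier == "high" for e in effects)
        line.append(
            f"{m}: C={fit.c_statistic:.3f}, outliers {n_low} low / {n_high} high"
            + (" (penalized)" if fit.penalized else "")
        )
    print(" | ".join(line))
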