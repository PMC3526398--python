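#!/usr/bin/env python
"""Apply the three counting rules and report crude mortality.

Reads the episodes from 02, writes one observation table per measure plus
per-hospital crude mortality, and prints the overall crude percentages with
the between-hospital ranges (the Table-4-style view).
"""

from pathlib import Path

import pandas as pd

from hospmort.episode_builder import read_episodes
from hospmort.mortality_measures import (
    compute_measure,
    crude_mortality,
    write_measure_tables,
)

ROOT = Path(__file__).resolve().parents[1] / "results"

for cond in ("AMI", "stroke", "hip_fracture"):
    episodes = read_episodes(ROOT / "episodes" / cond / "episodes.csv")
    out = ROOT / "measures" / cond
    tables = [compute_measure(m, episodes) for m in ("W30D", "S30D", "IH30D")]
    write_measure_tables(out, tables)
    crude_rows = []
    line = [cond]
    for t in tables:
        per_hosp, overall = crude_mortality(t)
        per_hosp.insert(0, "measure_id", t.measure_id)
        crude_rows.append(per_hosp)
        lo, hi = per_hosp["crude_mortality"].min(), per_hosp["crude_mortality"].max()
        line.append(
            f"{t.measure_id} {100 * overall:.1f}% ({100 * lo:.1f}-{100 * hi:.1f})"
        )
    pd.concat(crude_rows, ignore_index=True).to_csv(
        out / "crude_mortality.csv", index=False, float_format="%.10g"
    )
    print(" | ".join(line))
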