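#!/usr/bin/env python
"""Apply exclusions and chain admissions into episodes of care.

Reads the registries written by 01, writes ``episodes.csv`` +
``exclusions.csv`` and a descriptive cohort summary per condition, and prints
the Table-2-style margins (time, place and cause of death).
"""

import json
from pathlib import Path

from hospmort.episode_builder import (
    apply_exclusions,
    build_episodes,
    filter_hospitals_by_volume,
    study_years,
    write_episodes,
)
from hospmort.mortality_measures import summarize_cohort
from hospmort.synthetic_registry import read_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"

for cond in ("AMI", "stroke", "hip_fracture"):
    admissions, vitals = read_cohort(ROOT / "registry" / cond)
    retained, log = apply_exclusions(admissions, cond)
    retained, dropped = filter_hospitals_by_volume(
        retained, 20, years=study_years(retained)
    )
    episodes = build_episodes(retained, vitals)
    out = ROOT / "episodes" / cond
    write_episodes(out, episodes, log)
    s = summarize_cohort(episodes)
    with open(out / "cohort_summary.json", "w") as fh:
        json.dump(s, fh, indent=2, sort_keys=True)
    print(
        f"{cond}: {s['n_episodes']} episodes ({s['transfer_pct']:.1f}% transferred, "
        f"{len(dropped)} low-volume hospitals dropped) | deaths <=30d "
        f"{s['deaths_by_interval']['le30']['pct_of_episodes']:.1f}%, of which "
        f"out-of-hospital {s['place_of_death_30d']['out_of_hospital']['pct_of_30d_deaths']:.1f}% "
        f"and cause-matched {s['cause_match_30d']['pct_of_30d_deaths']:.1f}%; "
        f"mean LOS {s['mean_los_days']:.1f} d"
    )
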