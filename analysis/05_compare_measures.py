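#!/usr/bin/env python
"""Compare S30D and IH30D hospital profiles against the W30D reference.

Reads the effect tables from 04 and the episodes from 02 (for hospital mean
LOS and size categories), writes comparison JSONs, outlier cross-tabs and a
back-to-back shift-count chart per condition, and prints Spearman
correlations, outlier-change fractions and the category association tests.
"""

import json
from pathlib import Path

import pandas as pd

from hospmort.episode_builder import read_episodes
from hospmort.measure_comparison import compare_measures
from hospmort.mortality_measures import mean_los_by_hospital

ROOT = Path(__file__).resolve().parents[1] / "results"


def shift_barplot(results, path):
    """Back-to-back horizontal bars of shift counts, one panel per pair."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = ["none", "minor", "moderate", "major"]
    fig, axes = plt.subplots(1, len(results), figsize=(4 * len(results), 3), sharey=True)
    for ax, (name, res) in zip([axes] if len(results) == 1 else axes, results.items()):
        lower = [res.shift_counts.get((c, "toward_lower_mortality"), 0) for c in cats]
        higher = [res.shift_counts.get((c, "toward_higher_mortality"), 0) for c in cats]
        none_n = res.shift_counts.get(("none", None), 0)
        y = range(len(cats))
        ax.barh(y, [none_n] + lower[1:], color="white", edgecolor="black")
        ax.barh(y, [0] + [-v for v in higher[1:]], color="black")
        ax.axvline(0, color="black", lw=0.8)
        ax.set_yticks(list(y), cats)
        ax.set_title(name, fontsize=9)
        ax.invert_yaxis()
    fig.suptitle("filled = toward higher mortality rank, open = toward lower / none")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


for cond in ("AMI", "stroke", "hip_fracture"):
    episodes = read_episodes(ROOT / "episodes" / cond / "episodes.csv")
    los = mean_los_by_hospital(episodes)
    hosp = pd.read_csv(ROOT / "registry" / cond / "hospitals.csv")
    categories = dict(zip(hosp["hospital_id"], hosp["category"]))
    effects = {
        m: pd.read_csv(ROOT / "effects" / cond / f"effects_{m}.csv")
        for m in ("W30D", "S30D", "IH30D")
    }
    out = ROOT / "comparisons" / cond
    out.mkdir(parents=True, exist_ok=True)
    results = {}
    line = [cond]
    for other in ("S30D", "IH30D"):
        a, b = effects["W30D"], effects[other]
        common = set(a["hospital_id"]) & set(b["hospital_id"])
        sel = lambda df, col: {  # noqa: E731
            h: v for h, v in zip(df["hospital_id"], df[col]) if h in common
        }
        res = compare_measures(
            sel(a, "rank"), sel(b, "rank"), sel(a, "outlier"), sel(b, "outlier"),
            ("W30D", other),
            categories={h: c for h, c in categories.items() if h in common},
            mean_los={h: v for h, v in los.items() if h in common},
        )
        results[f"{other} vs W30D"] = res
        name = f"{other}_vs_W30D"
        with open(out / f"comparison_{name}.json", "w") as fh:
            json.dump(res.to_dict(), fh, indent=2, sort_keys=True)
        res.outlier_crosstab.to_csv(out / f"crosstab_{name}.csv")
        line.append(
            f"{other}: r={res.spearman_r:.2f}, outlier change "
            f"{100 * res.change_fraction:.1f}%, r(LOS)="
            f"{res.correlation_with_los:.2f}, ANOVA p={res.anova_p:.2f}, "
            f"Fisher p={res.fisher_p:.2f}"
        )
    shift_barplot(results, out / "shift_counts.png")
    print(" | ".join(line))
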