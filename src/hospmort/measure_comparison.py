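"""Stability of hospital profiles across mortality measures.

Compares a measure's hospital ranking and outlier pattern against a reference
measure: Spearman rank correlation, per-hospital rank shifts bucketed as none /
minor (1-5) / moderate (6-10) / major (>10) with direction, the 3x3 outlier
cross-tabulation with its off-diagonal change fraction, correlation of ranks
with hospital mean length of stay, a one-way ANOVA of absolute rank shifts
across hospital size categories, and an exact (Fisher) test of change/no-change
in outlier status by category.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import rankdata

OUTLIER_LEVELS = ("high", "medium", "low")
SHIFT_CATEGORIES = ("none", "minor", "moderate", "major")
DIRECTIONS = ("toward_lower_mortality", "toward_higher_mortality")


@dataclass
class ComparisonResult:
    measure_pair: tuple[str, str]  # (reference, comparator)
    spearman_r: float | None
    shift_counts: dict  # {(category, direction or None): int}
    shifts: pd.DataFrame  # per-hospital d, category, direction
    outlier_crosstab: pd.DataFrame | None  # rows = reference status, cols = comparator
    change_fraction: float | None
    correlation_with_los: float | None = None
    anova_F: float | None = None
    anova_p: float | None = None
    fisher_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "measure_pair": list(self.measure_pair),
            "spearman_r": self.spearman_r,
            "shift_counts": {
                f"{c}|{d}" if d else c: int(n) for (c, d), n in self.shift_counts.items()
            },
            "outlier_crosstab": (
                None if self.outlier_crosstab is None else self.outlier_crosstab.to_dict()
            ),
            "change_fraction": self.change_fraction,
            "correlation_with_los": self.correlation_with_los,
            "anova_F": self.anova_F,
            "anova_p": self.anova_p,
            "fisher_p": self.fisher_p,
        }


def _aligned(a: dict, b: dict) -> tuple[list, np.ndarray, np.ndarray]:
    if set(a) != set(b):
        raise ValueError("hospital sets differ between the two inputs")
    ids = sorted(a)
    return ids, np.array([a[i] for i in ids], float), np.array([b[i] for i in ids], float)


def spearman_rank_correlation(ranks_a: dict, ranks_b: dict) -> float | None:
    """Pearson correlation of the two (tie-averaged) rank vectors."""
    ids, ra, rb = _aligned(ranks_a, ranks_b)
    if len(ids) < 3:
        raise ValueError("need at least 3 hospitals")
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        warnings.warn("constant rank vector; Spearman correlation undefined")
        return None
    return float(np.corrcoef(ra, rb)[0, 1])


def categorize_shifts(ranks_a: dict, ranks_b: dict) -> tuple[dict, pd.DataFrame]:
    """Bucket per-hospital rank shifts d = rank_b − rank_a.

    |d| = 0 → none; 0 < |d| ≤ 5 → minor; 5 < |d| ≤ 10 → moderate; |d| > 10 →
    major.  Negative d (toward rank 1) is a shift toward lower mortality.
    Returns ``(counts, per_hospital_frame)`` where counts keys are
    ``(category, direction)`` with ``direction=None`` for "none".
    """
    ids, ra, rb = _aligned(ranks_a, ranks_b)
    d = rb - ra
    ad = np.abs(d)
    cat = np.where(ad == 0, "none", np.where(ad <= 5, "minor", np.where(ad <= 10, "moderate", "major")))
    direction = np.where(d < 0, DIRECTIONS[0], np.where(d > 0, DIRECTIONS[1], ""))
    frame = pd.DataFrame(
        {"hospital_id": ids, "d": d, "category": cat, "direction": direction}
    )
    counts: dict = {("none", None): int((cat == "none").sum())}
    for c in SHIFT_CATEGORIES[1:]:
        for dr in DIRECTIONS:
            counts[(c, dr)] = int(((cat == c) & (direction == dr)).sum())
    return counts, frame


def outlier_crosstab(
    status_ref: dict, status_other: dict
) -> tuple[pd.DataFrame, float]:
    """3x3 outlier cross-tab (rows = reference measure) and change fraction.

    The change fraction is the off-diagonal share: 1 − trace/total.
    """
    ids, _, _ = _aligned(
        {k: 0.0 for k in status_ref}, {k: 0.0 for k in status_other}
    )
    tab = pd.DataFrame(0, index=list(OUTLIER_LEVELS), columns=list(OUTLIER_LEVELS))
    for i in ids:
        tab.loc[status_ref[i], status_other[i]] += 1
    total = tab.to_numpy().sum()
    change = 1.0 - np.trace(tab.to_numpy()) / total
    return tab, float(change)


def crosstab_change_fraction(matrix) -> float:
    """Change fraction of an already-tabulated square outlier cross-tab."""
    m = np.asarray(matrix, dtype=float)
    return float(1.0 - np.trace(m) / m.sum())


def anova_abs_shift_by_category(
    abs_shifts: dict, categories: dict
) -> tuple[float | None, float | None]:
    """One-way fixed-effects ANOVA of |rank shift| across hospital categories."""
    ids = sorted(abs_shifts)
    if set(ids) != set(categories):
        raise ValueError("hospital sets differ")
    groups: dict = {}
    for i in ids:
        groups.setdefault(categories[i], []).append(abs_shifts[i])
    usable = {c: np.asarray(v, float) for c, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        warnings.warn("ANOVA degenerate: need >=2 categories with >=2 hospitals")
        return None, None
    allv = np.concatenate(list(usable.values()))
    grand = allv.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in usable.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in usable.values())
    dfb = len(usable) - 1
    dfw = allv.size - len(usable)
    if ssw <= 0:
        if ssb <= 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ssb / dfb) / (ssw / dfw)
    p = float(f_dist.sf(F, dfb, dfw))
    return float(F), p


def fisher_exact_change_by_category(table) -> float:
    """Exact p for a 2 x C change/no-change by category table.

    Enumerates all tables with the observed margins; the p-value sums the
    probabilities of tables no more probable than the observed one under the
    multivariate hypergeometric null.  A zero margin gives p = 1 by
    convention.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or np.any(t < 0):
        raise ValueError("table must be 2 x C with nonnegative integers")
    col = t.sum(axis=0)
    row = t.sum(axis=1)
    N = int(t.sum())
    if row.min() == 0 or (col > 0).sum() < 2:
        warnings.warn("degenerate margins; Fisher exact p = 1 by convention")
        return 1.0
    r1 = int(row[0])

    def log_prob(x: tuple[int, ...]) -> float:
        # log of prod_j C(col_j, x_j) / C(N, r1)
        lp = -(math.lgamma(N + 1) - math.lgamma(r1 + 1) - math.lgamma(N - r1 + 1))
        for cj, xj in zip(col, x):
            lp += math.lgamma(cj + 1) - math.lgamma(xj + 1) - math.lgamma(cj - xj + 1)
        return lp

    obs_lp = log_prob(tuple(int(v) for v in t[0]))
    total = 0.0
    p_extreme = 0.0
    for x in product(*(range(int(c) + 1) for c in col)):
        if sum(x) != r1:
            continue
        lp = log_prob(x)
        pr = math.exp(lp)
        total += pr
        if lp <= obs_lp + 1e-9:
            p_extreme += pr
    # normalization guards rounding; total should be 1
    return float(min(1.0, p_extreme / total))


def correlate_with_los(ranks: dict, mean_los: dict) -> float | None:
    """Spearman correlation between measure ranks and hospital mean LOS."""
    ids, rv, lv = _aligned(ranks, mean_los)
    if np.ptp(rv) == 0 or np.ptp(lv) == 0:
        warnings.warn("constant input; LOS correlation undefined")
        return None
    return float(np.corrcoef(rankdata(rv), rankdata(lv))[0, 1])


def compare_measures(
    ranks_ref: dict,
    ranks_other: dict,
    status_ref: dict | None,
    status_other: dict | None,
    pair: tuple[str, str],
    categories: dict | None = None,
    mean_los: dict | None = None,
) -> ComparisonResult:
    """Full comparison of one measure against the reference measure.

    ``status_ref``/``status_other`` may be None (e.g. unadjusted rankings),
    in which case the outlier cross-tab, change fraction and Fisher test are
    omitted.
    """
    r = spearman_rank_correlation(ranks_ref, ranks_other)
    counts, frame = categorize_shifts(ranks_ref, ranks_other)
    tab = change = None
    if status_ref is not None and status_other is not None:
        tab, change = outlier_crosstab(status_ref, status_other)
    res = ComparisonResult(
        measure_pair=pair,
        spearman_r=r,
        shift_counts=counts,
        shifts=frame,
        outlier_crosstab=tab,
        change_fraction=change,
    )
    if mean_los is not None:
        res.correlation_with_los = correlate_with_los(ranks_other, mean_los)
    if categories is not None:
        abs_shifts = dict(zip(frame["hospital_id"], np.abs(frame["d"])))
        res.anova_F, res.anova_p = anova_abs_shift_by_category(abs_shifts, categories)
        if status_ref is not None and status_other is not None:
            changed = {h: status_ref[h] != status_other[h] for h in status_ref}
            cats_present = sorted(set(categories.values()))
            table = np.zeros((2, len(cats_present)), dtype=int)
            for h, c in categories.items():
                table[0 if changed[h] else 1, cats_present.index(c)] += 1
            res.fisher_p = fisher_exact_change_by_category(table)
    return res
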