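"""Case-mix-adjusted hospital effects via weighted logistic regression.

The model regresses the per-observation outcome on a B-spline in age, sex,
disease stage, and hospital under sum-to-zero (deviation) coding, so each
hospital's coefficient is its log-odds deviation from the mean of all
hospitals; the constrained J-th effect is recovered as minus the sum of the
fitted J−1 contrasts.  Observation weights carry the fractional attribution of
the time-weighted measure (weights are 1 for the other measures).

Fitting maximizes the weighted binomial log-likelihood
``sum_i w_i [y_i log p_i + (1 - y_i) log(1 - p_i)]`` by iteratively
reweighted least squares (Newton scoring with step halving).  When the fit
quasi-separates — hospitals with zero (or all) weighted events push a contrast
to infinity — a Firth-type penalized refit (Jeffreys-prior score adjustment,
generalized to observation weights) keeps every hospital classifiable.

Hospitals are flagged as outliers from the Wald statistic ``z = beta / se``:
low mortality below the lower normal tail quantile, high above the upper one,
strict inequalities.  Ranks are 1 = lowest mortality with average ranks on
ties.  Model discrimination is the weighted concordance (C-statistic).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy.special import expit
from scipy.stats import norm, rankdata

from hospmort.mortality_measures import MeasureTable

logger = logging.getLogger(__name__)

_HOSP_PREFIX = "hosp:"


class RankDeficiencyError(np.linalg.LinAlgError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


@dataclass
class ModelSpec:
    """Covariate specification for the adjustment model.

    ``age_knots=None`` places interior knots at the 25/50/75 age percentiles
    of the analysis table (cubic by default).
    """

    age_degree: int = 3
    age_knots: tuple | None = None
    tail: float = 0.05
    window_days: int = 30

    def __post_init__(self):
        if self.age_degree < 1:
            raise ValueError("age_degree must be >= 1")
        if self.age_knots is not None:
            k = list(self.age_knots)
            if any(b <= a for a, b in zip(k, k[1:])):
                raise ValueError("age_knots must be strictly increasing")
        if not 0.0 < self.tail < 0.5:
            raise ValueError("tail must be in (0, 0.5)")


@dataclass
class ModelFit:
    params: pd.Series
    cov: pd.DataFrame
    converged: bool
    n_iterations: int
    log_likelihood: float
    penalized: bool
    fitted_probs: np.ndarray
    hospital_ids: list[str]
    c_statistic: float | None = None
    trace: list = field(default_factory=list)


@dataclass
class HospitalEffect:
    hospital_id: str
    beta: float
    se: float
    z: float
    outlier: str | None = None
    rank: float | None = None


def build_design(
    table: MeasureTable | pd.DataFrame, spec: ModelSpec | None = None
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, list[str]]:
    """Design matrix aligned to observations.

    Returns ``(X, y, w, hospital_ids)``.  Columns: intercept; B-spline basis
    in age (degree + n_knots columns, the full basis less the function
    absorbed by the intercept); female indicator; stage indicators (first
    level reference, empty levels dropped with a warning); and J−1 deviation
    contrasts for hospital with the last hospital's row coded −1 throughout.
    """
    obs = table.observations if isinstance(table, MeasureTable) else table
    spec = spec or ModelSpec()
    hospitals = sorted(obs["hospital_id"].unique())
    if len(hospitals) < 2:
        raise ValueError("need at least 2 hospitals")

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(obs))}

    age = obs["age_years"].to_numpy(dtype=float)
    if np.ptp(age) <= 0:
        warnings.warn("age is constant; spline columns collinear and omitted")
    else:
        knots = spec.age_knots
        if knots is None:
            qs = np.percentile(age, [25, 50, 75])
            knots = tuple(np.unique(qs[(qs > age.min()) & (qs < age.max())]))
        basis = dmatrix(
            "bs(x, knots=knots, degree=degree, include_intercept=False) - 1",
            {"x": age, "knots": tuple(knots), "degree": spec.age_degree},
            return_type="matrix",
        )
        for j in range(basis.shape[1]):
            cols[f"age_bs{j + 1}"] = np.asarray(basis[:, j]).ravel()

    sex = obs["sex"].to_numpy()
    if len(np.unique(sex)) > 1:
        cols["sex_F"] = (sex == "F").astype(float)

    stage = obs["stage"].astype(str).to_numpy()
    levels = [s for s in sorted(np.unique(stage))]
    counts = {s: int((stage == s).sum()) for s in levels}
    empty = [s for s, c in counts.items() if c == 0]
    if empty:
        warnings.warn(f"stage level(s) with zero observations dropped: {empty}")
        levels = [s for s in levels if counts[s] > 0]
    for s in levels[1:]:
        cols[f"stage[{s}]"] = (stage == s).astype(float)

    hosp = obs["hospital_id"].to_numpy()
    last = hospitals[-1]
    is_last = (hosp == last).astype(float)
    for h in hospitals[:-1]:
        cols[f"{_HOSP_PREFIX}{h}"] = (hosp == h).astype(float) - is_last

    X = pd.DataFrame(cols, index=obs.index)
    y = obs["outcome"].to_numpy(dtype=float)
    w = obs["weight"].to_numpy(dtype=float)
    return X, y, w, hospitals


def _weighted_loglik(y, w, p):
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(np.sum(w * (y * np.log(p) + (1 - y) * np.log1p(-p))))


def fit_weighted_logistic(
    X: pd.DataFrame,
    y: np.ndarray,
    w: np.ndarray,
    hospital_ids: list[str] | None = None,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
    penalized: bool = False,
) -> ModelFit:
    """Weighted logistic ML by IRLS, with Firth-penalized fallback.

    Convergence when the largest absolute score component falls below
    ``score_tol`` or the relative log-likelihood change below ``ll_tol``
    (at most ``max_iter`` iterations).  If the unpenalized fit fails to
    converge with any \\|linear predictor\\| > 15 (quasi-separation), the model
    is refit with the Firth-type penalty and ``penalized=True`` is surfaced.
    """
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")

    # rank check, naming offending columns
    q, r = np.linalg.qr(Xv * np.sqrt(w)[:, None])
    diag = np.abs(np.diag(r))
    bad = diag < 1e-8 * max(diag.max(), 1.0)
    if bad.any():
        names = [X.columns[i] for i in np.flatnonzero(bad)]
        raise RankDeficiencyError(f"design is rank deficient in column(s): {names}")

    n, k = Xv.shape
    beta = np.zeros(k)
    if "intercept" in X.columns:
        pbar = np.clip(np.average(y, weights=w), 1e-6, 1 - 1e-6)
        beta[X.columns.get_loc("intercept")] = np.log(pbar / (1 - pbar))

    def _objective(beta):
        lp = Xv @ beta
        p = expit(lp)
        ll = _weighted_loglik(y, w, p)
        Wd = np.clip(w * p * (1 - p), 1e-12, None)
        M = Xv.T @ (Xv * Wd[:, None])
        if penalized:
            sign, logdet = np.linalg.slogdet(M)
            ll = ll + 0.5 * logdet
        return lp, p, Wd, M, ll

    lp, p, Wd, M, ll = _objective(beta)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = w * (y - p)
        if penalized:
            # hat diagonal of the weighted information
            S = np.linalg.solve(M, Xv.T)
            h = Wd * np.einsum("ij,ji->i", Xv, S)
            score = Xv.T @ (resid + h * (0.5 - p))
        else:
            score = Xv.T @ resid
        max_score = float(np.abs(score).max())
        trace.append((it, ll, max_score))
        if max_score < score_tol:
            converged = True
            break
        delta = np.linalg.solve(M, score)
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            lp2, p2, Wd2, M2, ll2 = _objective(cand)
            if np.isfinite(ll2) and ll2 >= ll - 1e-12:
                break
            step /= 2.0
        rel_change = abs(ll2 - ll) / (abs(ll) + 1e-12)
        beta, lp, p, Wd, M, ll = cand, lp2, p2, Wd2, M2, ll2
        if rel_change < ll_tol:
            converged = True
            break

    if not converged and not penalized:
        if np.abs(lp).max() > 15:
            logger.info("quasi-separation detected; refitting with Firth penalty")
            fit = fit_weighted_logistic(
                X, y, w, hospital_ids, max_iter, score_tol, ll_tol, penalized=True
            )
            fit.penalized = True
            return fit
        raise ConvergenceError(
            f"IRLS failed to converge in {max_iter} iterations", trace
        )
    if not converged and penalized:
        # penalized likelihood is well behaved; accept the best iterate but say so
        logger.warning("penalized IRLS hit max_iter; returning last iterate")

    cov = np.linalg.inv(M)
    return ModelFit(
        params=pd.Series(beta, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        converged=converged,
        n_iterations=it,
        log_likelihood=_weighted_loglik(y, w, p),
        penalized=penalized,
        fitted_probs=p,
        hospital_ids=list(hospital_ids or []),
        trace=trace,
    )


def hospital_deviations(fit: ModelFit) -> list[HospitalEffect]:
    """All J hospital deviations (fitted J−1 contrasts plus the implied one).

    The implied effect is −sum of the contrasts, with standard error from the
    contrast covariance block (var = 1' V 1).
    """
    names = [c for c in fit.params.index if c.startswith(_HOSP_PREFIX)]
    if not names:
        raise ValueError("fit has no hospital contrast columns")
    ids = [c[len(_HOSP_PREFIX):] for c in names]
    betas = fit.params[names].to_numpy()
    V = fit.cov.loc[names, names].to_numpy()
    ses = np.sqrt(np.diag(V))
    last_id = (
        fit.hospital_ids[-1]
        if fit.hospital_ids
        else "(constrained)"
    )
    effects = [
        HospitalEffect(i, float(b), float(s), float(b / s))
        for i, b, s in zip(ids, betas, ses)
    ]
    b_last = -betas.sum()
    se_last = float(np.sqrt(np.ones(len(names)) @ V @ np.ones(len(names))))
    effects.append(HospitalEffect(last_id, float(b_last), se_last, float(b_last / se_last)))
    return effects


def classify_outliers(
    effects: list[HospitalEffect], tail: float = 0.05
) -> list[HospitalEffect]:
    """Flag low/high mortality outliers from the normal tail quantiles of Z."""
    if not 0.0 < tail < 0.5:
        raise ValueError("tail must be in (0, 0.5)")
    lo, hi = norm.ppf(tail), norm.ppf(1.0 - tail)
    for e in effects:
        if e.z < lo:
            e.outlier = "low"
        elif e.z > hi:
            e.outlier = "high"
        else:
            e.outlier = "medium"
    return effects


def rank_hospitals(
    values: dict[str, float], direction: str = "ascending"
) -> dict[str, float]:
    """Rank hospitals (1 = lowest mortality), average ranks on ties.

    ``direction='ascending'`` means smaller values (more negative deviations,
    lower crude proportions) get rank 1; ``'descending'`` reverses.
    """
    if not values:
        raise ValueError("empty values")
    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be 'ascending' or 'descending'")
    ids = sorted(values)
    v = np.array([values[i] for i in ids], dtype=float)
    if direction == "descending":
        v = -v
    r = rankdata(v, method="average")
    return dict(zip(ids, r.astype(float)))


def c_statistic(
    probs: np.ndarray, outcomes: np.ndarray, weights: np.ndarray | None = None
) -> float | None:
    """Weighted concordance over (death, survivor) pairs.

    Pair weight is ``w_i * w_j``; ties in the predicted probability count 0.5.
    Returns None (with a warning) if there are no deaths or no survivors.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    uniq, inv = np.unique(p, return_inverse=True)
    dw = np.bincount(inv, weights=w * y, minlength=uniq.size)
    sw = np.bincount(inv, weights=w * (1 - y), minlength=uniq.size)
    D, S = dw.sum(), sw.sum()
    if D <= 0 or S <= 0:
        warnings.warn("C-statistic undefined: no deaths or no survivors")
        return None
    cum_sw_below = np.concatenate(([0.0], np.cumsum(sw)[:-1]))
    conc = float(np.sum(dw * cum_sw_below) + 0.5 * np.sum(dw * sw))
    return conc / float(D * S)


def effects_to_frame(effects: list[HospitalEffect], penalized: bool = False) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "hospital_id": [e.hospital_id for e in effects],
            "beta": [e.beta for e in effects],
            "se": [e.se for e in effects],
            "z": [e.z for e in effects],
            "outlier": [e.outlier for e in effects],
            "rank": [e.rank for e in effects],
            "penalized": penalized,
        }
    )


def adjust_measure(
    table: MeasureTable, spec: ModelSpec | None = None
) -> tuple[ModelFit, list[HospitalEffect]]:
    """Fit the adjustment model for one measure and profile the hospitals.

    Builds the design, fits (penalized from the start when some hospital has
    zero or all weighted events, which would quasi-separate), recovers all J
    deviations, attaches Wald Z, outlier category and rank (1 = lowest
    adjusted mortality), and computes the weighted C-statistic.
    """
    spec = spec or ModelSpec()
    X, y, w, hospitals = build_design(table, spec)
    obs = table.observations
    ev = obs.assign(wy=obs["weight"] * obs["outcome"]).groupby("hospital_id")[
        ["wy", "weight"]
    ].sum()
    degenerate = (ev["wy"] <= 0) | (ev["wy"] >= ev["weight"])
    fit = fit_weighted_logistic(
        X, y, w, hospital_ids=hospitals, penalized=bool(degenerate.any())
    )
    effects = classify_outliers(hospital_deviations(fit), spec.tail)
    ranks = rank_hospitals({e.hospital_id: e.beta for e in effects})
    for e in effects:
        e.rank = ranks[e.hospital_id]
    fit.c_statistic = c_statistic(fit.fitted_probs, y, w)
    return fit, effects
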