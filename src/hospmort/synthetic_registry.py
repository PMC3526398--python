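"""Synthetic hospital admission registry with known hospital effects.

Emulates the structure of a national patient-administrative extract for acute
AMI, stroke and hip-fracture admissions over several years: hospitals in three
size categories, admission/discharge timestamps at 1-hour resolution, transfer
chains with inter-stay gaps under 24 hours, a death register with date and
cause of death, and case-mix covariates (age, sex, disease stage).

Each hospital carries a latent log-odds deviation ("true effect") from the
all-hospital mean.  An episode's death probability is
``expit(b0 + sum_h w_h * effect_h + case-mix terms)`` where ``w_h`` is the
fraction of in-hospital time (truncated at 30 days) spent at hospital ``h`` —
the estimand of the time-weighted mortality measure, so parameter recovery is a
meaningful end-to-end check.  The intercept ``b0`` is calibrated per run by
root finding so the realized marginal 30-day mortality matches the configured
target.

All randomness flows from one ``numpy`` Generator seeded once per run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from hospmort.codes import CONDITIONS, NON_MATCHING_CODES, REFERRAL_CODES

CATEGORIES = ("small", "large", "university")

WINDOW_DAYS = 30.0


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class Hospital:
    hospital_id: str
    category: str
    true_effect: float  # log-odds deviation from the all-hospital mean (latent)


@dataclass
class SimulationConfig:
    """Parameters of one simulated condition-specific registry.

    Defaults for each condition come from :func:`default_config`; probabilities
    are marginal targets (transfer rate, 30-day mortality, out-of-hospital
    share of 30-day deaths, cause-match share), length-of-stay parameters are
    lognormal means in days, and ``hospital_effect_sd`` is the SD of the latent
    log-odds hospital deviations.
    """

    condition: str = "AMI"
    seed: int = 0
    n_hospitals: dict = field(
        default_factory=lambda: {"small": 34, "large": 16, "university": 5}
    )
    years: int = 5
    start_year: int = 1997
    patients_per_hospital_year: dict = field(
        default_factory=lambda: {"small": 101.0, "large": 264.0, "university": 380.0}
    )
    hospital_volume_jitter_sd: float = 0.25
    baseline_30d_mortality: float = 0.191
    hospital_effect_sd: float = 0.2
    center_effects: bool = True
    transfer_probability: float = 0.051
    second_transfer_probability: float = 0.025
    # rows = source category (small, large, university), columns = destination
    transfer_destination_matrix: np.ndarray = field(
        default_factory=lambda: _normalize_rows(
            [[4.7, 6.9, 29.6], [15.9, 4.7, 25.5], [5.4, 6.9, 0.4]]
        )
    )
    transfer_gap_hours: tuple = (1, 20)
    los_mean_days: float = 8.6
    los1_mean_days: float = 5.0
    los2_mean_days: float = 5.5
    los_sigma: float = 0.6
    age_mean: float = 72.0
    age_sd: float = 13.5
    age_range: tuple = (18.0, 105.0)
    female_fraction: float = 0.380
    stage_levels: tuple = ("3.1-3.3", "3.4-3.6", "3.7-3.9")
    stage_probs: tuple = (0.45, 0.35, 0.20)
    stage_log_odds: tuple = (0.0, 0.6, 1.2)
    age_log_odds_per_year: float = 0.05
    age_reference: float = 75.0
    female_log_odds: float = -0.05
    out_of_hospital_death_share: float = 0.111
    late_death_shares: tuple = (0.032, 0.059)  # marginal P(death in 31-90, 91-365 d)
    cause_match_probability: float = 0.738
    late_cause_match_probabilities: tuple = (0.317, 0.218)
    p_dead_on_arrival: float = 0.0
    p_elective: float = 0.0
    p_rehab: float = 0.0

    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigError(f"condition: unknown value {self.condition!r}")
        for name in (
            "baseline_30d_mortality",
            "transfer_probability",
            "second_transfer_probability",
            "female_fraction",
            "out_of_hospital_death_share",
            "cause_match_probability",
            "p_dead_on_arrival",
            "p_elective",
            "p_rehab",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: probability {v} outside [0, 1]")
        if set(self.n_hospitals) - set(CATEGORIES):
            raise ConfigError("n_hospitals: unknown category key")
        if sum(self.n_hospitals.values()) < 1:
            raise ConfigError("n_hospitals: need at least one hospital")
        if self.years < 1:
            raise ConfigError(f"years: must be >= 1, got {self.years}")
        if self.hospital_effect_sd < 0:
            raise ConfigError("hospital_effect_sd: must be >= 0")
        m = np.asarray(self.transfer_destination_matrix, dtype=float)
        if m.shape != (3, 3) or np.any(m < 0):
            raise ConfigError("transfer_destination_matrix: must be 3x3 nonnegative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ConfigError("transfer_destination_matrix: rows must sum to 1")
        if len(self.stage_levels) != len(self.stage_probs) or len(
            self.stage_levels
        ) != len(self.stage_log_odds):
            raise ConfigError("stage_levels/stage_probs/stage_log_odds: length mismatch")
        if not np.isclose(sum(self.stage_probs), 1.0, atol=1e-6):
            raise ConfigError("stage_probs: must sum to 1")
        if sum(self.late_death_shares) + self.baseline_30d_mortality >= 1.0:
            raise ConfigError("late_death_shares: total death share must be < 1")
        for name in ("los_mean_days", "los1_mean_days", "los2_mean_days", "los_sigma"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["transfer_destination_matrix"] = np.asarray(
            self.transfer_destination_matrix
        ).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        for key in (
            "transfer_gap_hours",
            "age_range",
            "stage_levels",
            "stage_probs",
            "stage_log_odds",
            "late_death_shares",
            "late_cause_match_probabilities",
        ):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "transfer_destination_matrix" in d:
            d["transfer_destination_matrix"] = np.asarray(
                d["transfer_destination_matrix"], dtype=float
            )
        return cls(**d)


def _normalize_rows(rows) -> np.ndarray:
    m = np.asarray(rows, dtype=float)
    return m / m.sum(axis=1, keepdims=True)


# Per-condition default parameter sets.  Hospital counts, transfer rates,
# marginal mortality, mean LOS, sex mix, out-of-hospital death shares and
# cause-match shares follow the published national registry margins; volumes
# are patients (admission chains) per hospital-year by category.
_CONDITION_DEFAULTS: dict[str, dict] = {
    "AMI": {},  # the dataclass defaults are the AMI scenario
    "stroke": dict(
        n_hospitals={"small": 38, "large": 16, "university": 5},
        patients_per_hospital_year={"small": 100.0, "large": 253.0, "university": 341.0},
        baseline_30d_mortality=0.176,
        transfer_probability=0.048,
        transfer_destination_matrix=_normalize_rows(
            [[8.9, 7.9, 12.4], [39.3, 6.2, 12.3], [6.2, 5.7, 1.1]]
        ),
        los_mean_days=14.0,
        los1_mean_days=5.5,
        los2_mean_days=14.5,
        age_mean=77.0,
        age_sd=12.5,
        female_fraction=0.498,
        stage_levels=("infarction", "haemorrhage"),
        stage_probs=(0.85, 0.15),
        stage_log_odds=(0.0, 1.0),
        out_of_hospital_death_share=0.165,
        late_death_shares=(0.045, 0.079),
        cause_match_probability=0.896,
        late_cause_match_probabilities=(0.676, 0.410),
    ),
    "hip_fracture": dict(
        n_hospitals={"small": 39, "large": 15, "university": 4},
        patients_per_hospital_year={"small": 81.0, "large": 232.0, "university": 346.0},
        baseline_30d_mortality=0.078,
        transfer_probability=0.066,
        transfer_destination_matrix=_normalize_rows(
            [[10.5, 12.2, 5.8], [58.2, 4.1, 1.7], [3.4, 1.8, 2.4]]
        ),
        los_mean_days=11.8,
        los1_mean_days=5.0,
        los2_mean_days=13.0,
        age_mean=81.0,
        age_sd=8.0,
        age_range=(65.0, 105.0),
        female_fraction=0.742,
        stage_levels=("1.1-1.2", "2.3-3.3"),
        stage_probs=(0.6, 0.4),
        stage_log_odds=(0.0, 0.8),
        out_of_hospital_death_share=0.510,
        late_death_shares=(0.065, 0.114),
        cause_match_probability=0.759,
        late_cause_match_probabilities=(0.382, 0.106),
    ),
}


def default_config(condition: str = "AMI", **overrides) -> SimulationConfig:
    """Default :class:`SimulationConfig` for one condition, with overrides."""
    if condition not in _CONDITION_DEFAULTS:
        raise ConfigError(f"condition: unknown value {condition!r}")
    kwargs = dict(_CONDITION_DEFAULTS[condition])
    kwargs["condition"] = condition
    kwargs.update(overrides)
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg


def generate_hospitals(config: SimulationConfig) -> list[Hospital]:
    """Draw the hospital roster with latent log-odds effects.

    Effects are Normal(0, hospital_effect_sd^2); under ``center_effects`` they
    are centered to mean zero within each size category (hence overall).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    hospitals: list[Hospital] = []
    idx = 1
    for cat in CATEGORIES:
        n = int(config.n_hospitals.get(cat, 0))
        if n == 0:
            continue
        eff = rng.normal(0.0, config.hospital_effect_sd, size=n)
        if config.center_effects and n > 0 and config.hospital_effect_sd > 0:
            eff = eff - eff.mean()
        for e in eff:
            hospitals.append(Hospital(f"H{idx:02d}", cat, float(e)))
            idx += 1
    return hospitals


def hospitals_to_frame(hospitals: list[Hospital]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "hospital_id": [h.hospital_id for h in hospitals],
            "category": [h.category for h in hospitals],
            "true_effect": [h.true_effect for h in hospitals],
        }
    )


def _truncnorm_rvs(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _lognormal_mean(mean_days: float, sigma: float, size, rng) -> np.ndarray:
    # lognormal parameterized by its arithmetic mean
    mu = np.log(mean_days) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, size=size)


def truncated_stay_weights(
    starts: np.ndarray, ends: np.ndarray, window_days: float = WINDOW_DAYS
) -> np.ndarray:
    """Fraction-of-time weights for stacked stays (rows = episodes).

    ``starts``/``ends`` are day offsets from the episode index time, NaN for
    absent stays.  Each stay is truncated at ``window_days``; weights are the
    truncated durations normalized to sum to 1 per row.
    """
    t = np.clip(np.fmin(ends, window_days) - np.fmin(starts, window_days), 0.0, None)
    t = np.where(np.isnan(t), 0.0, t)
    tot = t.sum(axis=1)
    # degenerate rows (no in-window time): equal weights over present stays
    present = ~np.isnan(starts)
    n_present = present.sum(axis=1)
    safe_tot = np.where(tot > 0, tot, 1.0)
    w = t / safe_tot[:, None]
    eq = present / np.maximum(n_present, 1)[:, None]
    return np.where((tot > 0)[:, None], w, eq)


def generate_cohort(
    config: SimulationConfig, hospitals: list[Hospital]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one condition's registry.

    Returns ``(admissions, vitals, truth)``: one admissions row per hospital
    stay, one vitals row per death (date + underlying/contributing causes),
    and one truth row per episode holding the latent linear predictor, death
    probability and outcome.
    """
    config.validate()
    if not hospitals:
        raise ConfigError("hospitals: must be nonempty")
    rng = np.random.default_rng(config.seed + 1)

    cats = np.array([h.category for h in hospitals])
    effects = np.array([h.true_effect for h in hospitals])
    J = len(hospitals)
    cat_idx = {c: np.flatnonzero(cats == c) for c in CATEGORIES}

    # expected volume per hospital: category mean with mean-preserving jitter
    jit = config.hospital_volume_jitter_sd
    vol = np.array(
        [config.patients_per_hospital_year.get(h.category, 0.0) for h in hospitals]
    ) * rng.lognormal(-(jit**2) / 2.0, jit, size=J)
    if vol.sum() <= 0:
        raise ConfigError("patients_per_hospital_year: total volume is zero")
    n = int(round(vol.sum() * config.years))

    # --- index admission ---------------------------------------------------
    hosp0 = rng.choice(J, size=n, p=vol / vol.sum())
    origin = pd.Timestamp(f"{config.start_year}-01-01")
    total_hours = int(
        (pd.Timestamp(f"{config.start_year + config.years}-01-01") - origin)
        / pd.Timedelta(hours=1)
    )
    adm0_h = rng.integers(0, total_hours, size=n)

    # --- case mix ----------------------------------------------------------
    age = _truncnorm_rvs(
        config.age_mean, config.age_sd, config.age_range[0], config.age_range[1], n, rng
    )
    female = rng.random(n) < config.female_fraction
    stage_idx = rng.choice(len(config.stage_levels), size=n, p=config.stage_probs)

    # --- transfer chain (planned stays) -----------------------------------
    transfer = rng.random(n) < config.transfer_probability
    second = transfer & (rng.random(n) < config.second_transfer_probability)

    los = np.full((n, 3), np.nan)
    los[:, 0] = np.where(
        transfer,
        _lognormal_mean(config.los1_mean_days, config.los_sigma, n, rng),
        _lognormal_mean(config.los_mean_days, config.los_sigma, n, rng),
    )
    los2 = _lognormal_mean(config.los2_mean_days, config.los_sigma, n, rng)
    los3 = _lognormal_mean(config.los2_mean_days, config.los_sigma, n, rng)
    los[transfer, 1] = los2[transfer]
    los[second, 2] = los3[second]

    gap_lo, gap_hi = config.transfer_gap_hours
    gaps = rng.integers(int(gap_lo), int(gap_hi) + 1, size=(n, 2)).astype(float)

    dest_m = np.asarray(config.transfer_destination_matrix, dtype=float)
    hosp = np.full((n, 3), -1, dtype=int)
    hosp[:, 0] = hosp0

    def _draw_destination(source_hosp: np.ndarray) -> np.ndarray:
        """Destination hospital per row, category from the transition matrix,
        uniform within category, never the source hospital itself."""
        out = np.full(source_hosp.shape[0], -1, dtype=int)
        src_cat = cats[source_hosp]
        for ci, c in enumerate(CATEGORIES):
            rows = np.flatnonzero(src_cat == c)
            if rows.size == 0:
                continue
            dcat = rng.choice(3, size=rows.size, p=dest_m[ci])
            for di, d in enumerate(CATEGORIES):
                sel = rows[dcat == di]
                if sel.size == 0:
                    continue
                pool = cat_idx[d]
                if pool.size == 0:  # empty category: any other hospital
                    pool = np.arange(J)
                choice = pool[rng.integers(0, pool.size, size=sel.size)]
                clash = choice == source_hosp[sel]
                for k in np.flatnonzero(clash):
                    alt = pool[pool != source_hosp[sel[k]]]
                    if alt.size == 0:
                        alt = np.delete(np.arange(J), source_hosp[sel[k]])
                    choice[k] = alt[rng.integers(0, alt.size)]
                out[sel] = choice
        return out

    t_rows = np.flatnonzero(transfer)
    if t_rows.size:
        hosp[t_rows, 1] = _draw_destination(hosp0[t_rows])
    s_rows = np.flatnonzero(second)
    if s_rows.size:
        hosp[s_rows, 2] = _draw_destination(hosp[s_rows, 1])

    # stay boundaries in integer hours from the run origin
    adm_h = np.full((n, 3), np.nan)
    dis_h = np.full((n, 3), np.nan)
    adm_h[:, 0] = adm0_h
    dis_h[:, 0] = adm0_h + np.maximum(np.round(los[:, 0] * 24), 1)
    for k in (1, 2):
        m = ~np.isnan(los[:, k])
        adm_h[m, k] = dis_h[m, k - 1] + gaps[m, k - 1]
        dis_h[m, k] = adm_h[m, k] + np.maximum(np.round(los[m, k] * 24), 1)

    # --- outcome model -----------------------------------------------------
    starts_d = (adm_h - adm_h[:, [0]]) / 24.0
    ends_d = (dis_h - adm_h[:, [0]]) / 24.0
    w = truncated_stay_weights(starts_d, ends_d, WINDOW_DAYS)
    eff_stay = np.where(hosp >= 0, effects[np.maximum(hosp, 0)], 0.0)
    weighted_effect = (w * eff_stay).sum(axis=1)

    lp0 = (
        weighted_effect
        + config.age_log_odds_per_year * (age - config.age_reference)
        + config.female_log_odds * female
        + np.asarray(config.stage_log_odds)[stage_idx]
    )
    target = config.baseline_30d_mortality

    def _gap(b0: float) -> float:
        return float(expit(b0 + lp0).mean() - target)

    b0 = brentq(_gap, -20.0, 20.0, xtol=1e-10)
    p_death = expit(b0 + lp0)
    death30 = rng.random(n) < p_death

    # --- timing and place of death -----------------------------------------
    last_end = np.nanmax(ends_d, axis=1)
    oh_draw = rng.random(n) < config.out_of_hospital_death_share
    can_oh = last_end < WINDOW_DAYS
    oh_death = death30 & oh_draw & can_oh
    ih_death = death30 & ~oh_death

    death_h = np.full(n, np.nan)
    death_stay = np.full(n, -1, dtype=int)
    if oh_death.any():
        u = rng.random(int(oh_death.sum()))
        off = last_end[oh_death] + u * (WINDOW_DAYS - last_end[oh_death])
        death_h[oh_death] = adm0_h[oh_death] + np.round(off * 24)
    if ih_death.any():
        rows = np.flatnonzero(ih_death)
        t = np.clip(
            np.fmin(ends_d[rows], WINDOW_DAYS) - np.fmin(starts_d[rows], WINDOW_DAYS),
            0.0,
            None,
        )
        t = np.where(np.isnan(t), 0.0, t)
        tot = t.sum(axis=1)
        tot[tot <= 0] = 1.0
        cum = np.cumsum(t / tot[:, None], axis=1)
        u = rng.random(rows.size)
        k = (u[:, None] > cum).sum(axis=1).clip(0, 2)
        u2 = rng.random(rows.size)
        s = starts_d[rows, k]
        e = np.fmin(ends_d[rows, k], WINDOW_DAYS)
        off = s + u2 * np.maximum(e - s, 1.0 / 24.0)
        death_stay[rows] = k
        dh = adm0_h[rows] + np.round(off * 24)
        dh = np.maximum(dh, adm_h[rows, k] + 1)
        death_h[rows] = dh
        # truncate the episode at death: discharge at death, later stays void
        dis_h[rows, k] = dh
        for kk in (1, 2):
            drop = rows[k < kk]
            adm_h[drop, kk] = np.nan
            dis_h[drop, kk] = np.nan
            hosp[drop, kk] = -1

    # late deaths among 30-day survivors (placed out-of-hospital)
    r = rng.random(n)
    q1 = config.late_death_shares[0] / (1.0 - target)
    q2 = config.late_death_shares[1] / (1.0 - target)
    late1 = ~death30 & (r < q1)
    late2 = ~death30 & (r >= q1) & (r < q1 + q2)
    for mask, lo_d, hi_d in ((late1, 31.0, 90.0), (late2, 91.0, 365.0)):
        if not mask.any():
            continue
        lo = np.maximum(last_end[mask] + 2.0 / 24.0, lo_d)
        hi = np.maximum(lo + 1.0, hi_d)
        off = lo + rng.random(int(mask.sum())) * (hi - lo)
        death_h[mask] = adm0_h[mask] + np.round(off * 24)

    any_death = death30 | late1 | late2

    # --- cause of death -----------------------------------------------------
    p_match = np.where(
        death30,
        config.cause_match_probability,
        np.where(
            late1,
            config.late_cause_match_probabilities[0],
            config.late_cause_match_probabilities[1],
        ),
    )
    matches = rng.random(n) < p_match
    referral = np.array(REFERRAL_CODES[config.condition])
    other = np.array(NON_MATCHING_CODES)
    underlying = np.where(
        matches,
        referral[rng.integers(0, referral.size, size=n)],
        other[rng.integers(0, other.size, size=n)],
    )
    n_contrib = rng.integers(0, 3, size=n)
    contrib_pick = other[rng.integers(0, other.size, size=(n, 2))]

    # --- assemble tables ----------------------------------------------------
    patient_id = np.array([f"P{i:06d}" for i in range(n)])
    hosp_ids = np.array([h.hospital_id for h in hospitals])

    doa = rng.random(n) < config.p_dead_on_arrival
    elective = rng.random(n) < config.p_elective
    rehab = rng.random(n) < config.p_rehab
    primary_dx = referral[rng.integers(0, referral.size, size=n)]

    frames = []
    for k in range(3):
        m = hosp[:, k] >= 0
        if not m.any():
            continue
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_id[m],
                    "hospital_id": hosp_ids[hosp[m, k]],
                    "condition": config.condition,
                    "admission_datetime": origin
                    + pd.to_timedelta(adm_h[m, k].astype(int), unit="h"),
                    "discharge_datetime": origin
                    + pd.to_timedelta(dis_h[m, k].astype(int), unit="h"),
                    "admission_type": np.where(elective[m] & (k == 0), "elective", "acute"),
                    "primary_dx": primary_dx[m],
                    "secondary_dx": "",
                    "age_years": np.round(age[m], 2),
                    "sex": np.where(female[m], "F", "M"),
                    "stage": np.asarray(config.stage_levels)[stage_idx[m]],
                    "dead_on_arrival": doa[m] & (k == 0),
                    "rehab_flag": rehab[m] & (k > 0),
                }
            )
        )
    admissions = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["patient_id", "admission_datetime"], kind="mergesort")
        .reset_index(drop=True)
    )

    dm = np.flatnonzero(any_death)
    contribs = [
        "|".join(contrib_pick[i, : n_contrib[i]]) if n_contrib[i] else "" for i in dm
    ]
    vitals = pd.DataFrame(
        {
            "patient_id": patient_id[dm],
            "death_date": (
                origin + pd.to_timedelta(death_h[dm].astype(int), unit="h")
            ).normalize(),
            "underlying_cause": underlying[dm],
            "contributing_causes": contribs,
        }
    ).sort_values("patient_id", kind="mergesort", ignore_index=True)

    truth = pd.DataFrame(
        {
            "patient_id": patient_id,
            "index_hospital_id": hosp_ids[hosp0],
            "n_stays": (hosp >= 0).sum(axis=1),
            "linear_predictor": b0 + lp0,
            "weighted_true_effect": weighted_effect,
            "p_death_30d": p_death,
            "death_30d": death30.astype(int),
        }
    )
    return admissions, vitals, truth


# --- plain-text IO ----------------------------------------------------------

def write_cohort(
    out_dir: str | Path,
    admissions: pd.DataFrame,
    vitals: pd.DataFrame,
    truth: pd.DataFrame | None = None,
    hospitals: list[Hospital] | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    admissions.to_csv(out / "admissions.csv", index=False)
    vitals.to_csv(out / "vitals.csv", index=False, date_format="%Y-%m-%d")
    if truth is not None:
        truth.to_csv(out / "truth.csv", index=False, float_format="%.10g")
    if hospitals is not None:
        hospitals_to_frame(hospitals).to_csv(
            out / "hospitals.csv", index=False, float_format="%.10g"
        )


def read_cohort(in_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read ``admissions.csv`` and ``vitals.csv`` with parsed timestamps."""
    in_dir = Path(in_dir)
    admissions = pd.read_csv(
        in_dir / "admissions.csv",
        parse_dates=["admission_datetime", "discharge_datetime"],
        keep_default_na=False,
        na_values=[""],
    )
    admissions["secondary_dx"] = admissions["secondary_dx"].fillna("")
    vitals = pd.read_csv(
        in_dir / "vitals.csv",
        parse_dates=["death_date"],
        keep_default_na=False,
        na_values=[""],
    )
    vitals["contributing_causes"] = vitals["contributing_causes"].fillna("")
    return admissions, vitals
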