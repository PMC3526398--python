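"""The three 30-day mortality counting rules and cohort summaries.

* **W30D** — death within 30 days of the first day of the index admission,
  in or out of hospital; for transfer chains the outcome is attributed to each
  hospital with weight (in-hospital days at that hospital, truncated at day
  30) / (total truncated in-hospital days).
* **S30D** — same outcome definition, but episodes spanning two or more
  distinct hospitals are excluded entirely; weight 1.
* **IH30D** — in-hospital deaths only, with the 30-day clock restarting at
  each hospital's own first admission in the chain; earlier hospitals count
  the patient as a survivor, out-of-hospital deaths count nowhere; weight 1.

A death on day 30 (date difference exactly 30 days) counts as a death; day 31
is a survivor.  Durations are fractional days from timestamps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from hospmort.codes import cause_of_death_matches
from hospmort.episode_builder import EpisodeOfCare

logger = logging.getLogger(__name__)

MEASURES = ("W30D", "S30D", "IH30D")

_OBS_COLUMNS = [
    "measure_id",
    "hospital_id",
    "episode_id",
    "outcome",
    "weight",
    "age_years",
    "sex",
    "stage",
]


@dataclass
class MeasureTable:
    """One measure's observation rows: the (hospital, episode) atoms."""

    measure_id: str
    observations: pd.DataFrame
    window_days: int = 30

    def __len__(self) -> int:
        return len(self.observations)


def stay_weights(episode: EpisodeOfCare, window_days: int = 30) -> dict[str, float]:
    """Fraction-of-time weight per distinct hospital of one episode.

    Each stay is truncated at index time + ``window_days``; same-hospital
    stays pool.  If no in-hospital time falls inside the window (zero-length
    stays), equal weights over the distinct hospitals are returned with a
    warning.
    """
    index = episode.index_datetime
    totals: dict[str, float] = {}
    for s in episode.stays:
        start_d = (s.start - index) / pd.Timedelta(days=1)
        end_d = (s.end - index) / pd.Timedelta(days=1)
        t = max(0.0, min(end_d, window_days) - min(start_d, window_days))
        totals[s.hospital_id] = totals.get(s.hospital_id, 0.0) + t
    grand = sum(totals.values())
    if grand <= 0.0:
        logger.warning(
            "episode %s has zero truncated in-hospital time; equal weights used",
            episode.episode_id,
        )
        k = len(totals)
        return {h: 1.0 / k for h in totals}
    return {h: t / grand for h, t in totals.items()}


def _died_within(episode: EpisodeOfCare, window_days: int) -> int:
    d = episode.days_to_death()
    return int(d is not None and d <= window_days)


def _obs(measure_id, hospital_id, episode, outcome, weight):
    return {
        "measure_id": measure_id,
        "hospital_id": hospital_id,
        "episode_id": episode.episode_id,
        "outcome": int(outcome),
        "weight": float(weight),
        "age_years": episode.age_years,
        "sex": episode.sex,
        "stage": episode.stage,
    }


def compute_w30d(episodes: list[EpisodeOfCare], window_days: int = 30) -> MeasureTable:
    """Time-weighted in-and-out-of-hospital 30-day mortality observations.

    One row per (episode, distinct hospital); all hospitals of an episode
    share the episode's outcome, weights come from :func:`stay_weights`.
    """
    rows = []
    for ep in episodes:
        outcome = _died_within(ep, window_days)
        for h, w in stay_weights(ep, window_days).items():
            if w <= 0.0:
                # a hospital whose whole stay falls beyond the window gets no
                # share of the outcome and hence no observation
                continue
            rows.append(_obs("W30D", h, ep, outcome, w))
    return MeasureTable("W30D", pd.DataFrame(rows, columns=_OBS_COLUMNS), window_days)


def compute_s30d(episodes: list[EpisodeOfCare], window_days: int = 30) -> MeasureTable:
    """Single-hospital 30-day mortality observations (transfers excluded)."""
    rows = []
    for ep in episodes:
        if ep.n_distinct_hospitals >= 2:
            continue
        rows.append(_obs("S30D", ep.hospital_ids[0], ep, _died_within(ep, window_days), 1.0))
    return MeasureTable("S30D", pd.DataFrame(rows, columns=_OBS_COLUMNS), window_days)


def compute_ih30d(episodes: list[EpisodeOfCare], window_days: int = 30) -> MeasureTable:
    """In-hospital 30-day mortality, clock restarting at each hospital.

    A hospital counts the death iff the patient died in hospital during a stay
    at that hospital and the death date is within ``window_days`` of that
    hospital's own first admission date in the chain.
    """
    rows = []
    for ep in episodes:
        death_hospital = None
        if ep.death_in_hospital_stay is not None:
            death_hospital = ep.stays[ep.death_in_hospital_stay].hospital_id
        for h in ep.hospital_ids:
            outcome = 0
            if death_hospital == h:
                first_adm = min(
                    s.start for s in ep.stays if s.hospital_id == h
                ).normalize()
                days = (pd.Timestamp(ep.death_date) - first_adm) / pd.Timedelta(days=1)
                outcome = int(days <= window_days)
            rows.append(_obs("IH30D", h, ep, outcome, 1.0))
    return MeasureTable("IH30D", pd.DataFrame(rows, columns=_OBS_COLUMNS), window_days)


def compute_measure(
    measure_id: str, episodes: list[EpisodeOfCare], window_days: int = 30
) -> MeasureTable:
    fn = {"W30D": compute_w30d, "S30D": compute_s30d, "IH30D": compute_ih30d}
    if measure_id not in fn:
        raise ValueError(f"unknown measure {measure_id!r}")
    return fn[measure_id](episodes, window_days)


def crude_mortality(table: MeasureTable) -> tuple[pd.DataFrame, float]:
    """Weighted death proportion per hospital, plus the overall proportion.

    Per hospital: sum(weight * outcome) / sum(weight), with the total weight
    as the effective n.  Hospitals with zero total weight are excluded with a
    warning.
    """
    obs = table.observations
    if obs.empty:
        raise ValueError("empty measure table")
    grouped = obs.assign(wy=obs["weight"] * obs["outcome"]).groupby("hospital_id")
    agg = grouped.agg(total_weight=("weight", "sum"), deaths=("wy", "sum"))
    zero = agg["total_weight"] <= 0
    if zero.any():
        logger.warning("hospitals with zero total weight excluded: %s", list(agg.index[zero]))
        agg = agg[~zero]
    out = pd.DataFrame(
        {
            "hospital_id": agg.index,
            "crude_mortality": (agg["deaths"] / agg["total_weight"]).to_numpy(),
            "effective_n": agg["total_weight"].to_numpy(),
        }
    ).reset_index(drop=True)
    overall = float(obs["weight"].mul(obs["outcome"]).sum() / obs["weight"].sum())
    return out, overall


def mean_los_by_hospital(episodes: list[EpisodeOfCare]) -> dict[str, float]:
    """Mean stay length (days) per hospital, over all stays."""
    tot: dict[str, float] = {}
    cnt: dict[str, int] = {}
    for ep in episodes:
        for s in ep.stays:
            tot[s.hospital_id] = tot.get(s.hospital_id, 0.0) + s.los_days
            cnt[s.hospital_id] = cnt.get(s.hospital_id, 0) + 1
    return {h: tot[h] / cnt[h] for h in tot}


def summarize_cohort(episodes: list[EpisodeOfCare], window_days: int = 30) -> dict:
    """Descriptive summary: time, place and cause of death; transfers; LOS.

    Death intervals are counted from the index date at date precision:
    ``<=30``, ``31-90``, ``91-365`` days and alive beyond one year.  Place of
    death (for deaths within the window) distinguishes the first admission, a
    subsequent different hospital, and out-of-hospital.  The cause-of-death
    match flags deaths whose underlying or any contributing cause falls in the
    referral condition's code set.
    """
    n = len(episodes)
    intervals = {"le30": 0, "d31_90": 0, "d91_365": 0, "alive_gt_1y": 0}
    place = {"during_first_admission": 0, "different_hospital": 0, "out_of_hospital": 0}
    match_30d = 0
    match_1y = 0
    deaths_1y = 0
    n_transferred = 0
    total_los = 0.0

    for ep in episodes:
        if ep.transferred:
            n_transferred += 1
        total_los += ep.total_los_days()
        d = ep.days_to_death()
        if d is None or d > 365:
            intervals["alive_gt_1y"] += 1
            continue
        deaths_1y += 1
        matched = cause_of_death_matches(
            ep.underlying_cause, ep.contributing_causes, ep.condition
        )
        if matched:
            match_1y += 1
        if d <= window_days:
            intervals["le30"] += 1
            if matched:
                match_30d += 1
            if ep.death_in_hospital_stay is None:
                place["out_of_hospital"] += 1
            else:
                stay = ep.stays[ep.death_in_hospital_stay]
                if (
                    ep.death_in_hospital_stay == 0
                    or stay.hospital_id == ep.stays[0].hospital_id
                ):
                    place["during_first_admission"] += 1
                else:
                    place["different_hospital"] += 1
        elif d <= 90:
            intervals["d31_90"] += 1
        else:
            intervals["d91_365"] += 1

    deaths_30d = intervals["le30"]
    pct = lambda k, d: (100.0 * k / d) if d else None  # noqa: E731
    return {
        "n_episodes": n,
        "n_transferred": n_transferred,
        "transfer_pct": pct(n_transferred, n),
        "mean_los_days": total_los / n if n else None,
        "deaths_by_interval": {
            k: {"n": v, "pct_of_episodes": pct(v, n)} for k, v in intervals.items()
        },
        "place_of_death_30d": {
            k: {"n": v, "pct_of_30d_deaths": pct(v, deaths_30d)}
            for k, v in place.items()
        },
        "cause_match_30d": {"n": match_30d, "pct_of_30d_deaths": pct(match_30d, deaths_30d)},
        "cause_match_1y": {"n": match_1y, "pct_of_1y_deaths": pct(match_1y, deaths_1y)},
    }


def write_measure_tables(out_dir, tables: list[MeasureTable]) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t in tables:
        t.observations.to_csv(
            out / f"measure_{t.measure_id}.csv", index=False, float_format="%.10g"
        )
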