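"""Inclusion/exclusion rules and episode-of-care construction.

An episode of care is the chain of one patient's hospital stays in which each
stay begins no more than ``max_gap_hours`` (default 24 h, boundary inclusive)
after the previous discharge.  Episodes spanning two or more distinct
hospitals are "transferred" episodes.  Record-level exclusions (age cut-off,
dead on arrival, non-acute, rehabilitation, missing data) are applied first;
the first-admission-per-calendar-year rule is applied to chains, so a transfer
stay is never orphaned from its index admission.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXCLUSION_REASONS = (
    "underage",
    "dead_on_arrival",
    "non_acute",
    "readmission_same_year",
    "rehab",
    "low_volume_hospital",
    "missing_data",
)

MIN_AGE = {"AMI": 18.0, "stroke": 18.0, "hip_fracture": 65.0}

MANDATORY_FIELDS = (
    "patient_id",
    "hospital_id",
    "condition",
    "admission_datetime",
    "discharge_datetime",
    "admission_type",
    "age_years",
    "sex",
    "stage",
)


@dataclass(frozen=True)
class HospitalStay:
    hospital_id: str
    start: pd.Timestamp
    end: pd.Timestamp

    @property
    def los_days(self) -> float:
        return (self.end - self.start) / pd.Timedelta(days=1)


@dataclass
class EpisodeOfCare:
    episode_id: str
    patient_id: str
    condition: str
    stays: list[HospitalStay]
    age_years: float
    sex: str
    stage: str
    death_date: date | None = None
    death_in_hospital_stay: int | None = None
    underlying_cause: str | None = None
    contributing_causes: list[str] = field(default_factory=list)

    @property
    def index_datetime(self) -> pd.Timestamp:
        return self.stays[0].start

    @property
    def hospital_ids(self) -> list[str]:
        """Distinct hospitals in order of first appearance."""
        seen: list[str] = []
        for s in self.stays:
            if s.hospital_id not in seen:
                seen.append(s.hospital_id)
        return seen

    @property
    def n_distinct_hospitals(self) -> int:
        return len(self.hospital_ids)

    @property
    def transferred(self) -> bool:
        return self.n_distinct_hospitals >= 2

    def total_los_days(self) -> float:
        return sum(s.los_days for s in self.stays)

    def days_to_death(self) -> float | None:
        """Whole days from the index date to the death date (date precision)."""
        if self.death_date is None:
            return None
        return (pd.Timestamp(self.death_date) - self.index_datetime.normalize()) / pd.Timedelta(days=1)


def apply_exclusions(
    records: pd.DataFrame, condition: str, max_gap_hours: float = 24.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply record-level exclusion rules and the first-chain-per-year rule.

    Returns ``(retained, log)`` where ``log`` has one row per input record
    with a ``retained`` flag and a ``reason`` code for exclusions.  Age
    cut-offs are strict (``< 18`` years for AMI/stroke, ``< 65`` for hip
    fracture).  Chains are formed with the same ≤``max_gap_hours`` rule used
    for episode building so that only whole later chains of the same calendar
    year are dropped as ``readmission_same_year``.
    """
    if condition not in MIN_AGE:
        raise ValueError(f"unknown condition {condition!r}")
    rec = records.reset_index(drop=True)
    reason = pd.Series("", index=rec.index, dtype=object)

    missing = rec[list(MANDATORY_FIELDS)].isna().any(axis=1)
    reason[missing] = "missing_data"

    ok = reason == ""
    underage = ok & (rec["age_years"] < MIN_AGE[condition])
    reason[underage] = "underage"

    ok = reason == ""
    if "dead_on_arrival" in rec:
        doa = ok & rec["dead_on_arrival"].astype(bool)
        reason[doa] = "dead_on_arrival"

    ok = reason == ""
    non_acute = ok & (rec["admission_type"] != "acute")
    reason[non_acute] = "non_acute"

    ok = reason == ""
    if "rehab_flag" in rec:
        rh = ok & rec["rehab_flag"].astype(bool)
        reason[rh] = "rehab"

    # first chain per patient per calendar year among still-eligible records
    surv = rec[reason == ""].sort_values(
        ["patient_id", "admission_datetime"], kind="mergesort"
    )
    if not surv.empty:
        gap_h = (
            surv["admission_datetime"]
            - surv.groupby("patient_id", sort=False)["discharge_datetime"].shift()
        ) / pd.Timedelta(hours=1)
        new_chain = gap_h.isna() | (gap_h > max_gap_hours)
        chain = new_chain.groupby(surv["patient_id"], sort=False).cumsum() - 1
        surv = surv.assign(_chain=chain.astype(int))
        idx_time = surv.groupby(["patient_id", "_chain"])["admission_datetime"].transform(
            "min"
        )
        surv = surv.assign(_year=idx_time.dt.year, _index_time=idx_time)
        first_chain = (
            surv.drop_duplicates(["patient_id", "_chain"])
            .sort_values("_index_time", kind="mergesort")
            .drop_duplicates(["patient_id", "_year"])["_chain"]
        )
        keep_keys = set(
            zip(
                surv.loc[first_chain.index, "patient_id"],
                first_chain,
            )
        )
        dropped = [
            i
            for i, (p, c) in zip(surv.index, zip(surv["patient_id"], surv["_chain"]))
            if (p, c) not in keep_keys
        ]
        reason[dropped] = "readmission_same_year"

    log = pd.DataFrame(
        {
            "record_index": rec.index,
            "patient_id": rec["patient_id"],
            "retained": reason == "",
            "reason": reason,
        }
    )
    retained = rec[reason == ""].copy()
    return retained, log


def study_years(records: pd.DataFrame) -> set[int]:
    """Calendar years of the patients' index admissions.

    A transfer stay that begins just after New Year must not add a spurious
    study year, so years are taken from each patient's earliest admission.
    """
    first = records.groupby("patient_id")["admission_datetime"].min()
    return set(first.dt.year.unique())


def filter_hospitals_by_volume(
    records: pd.DataFrame, min_per_year: int = 20, years: set | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Keep hospitals with at least ``min_per_year`` admissions in every year.

    ``years`` defaults to all calendar years present in the data; a hospital
    with no admissions in one of the listed years fails the criterion.
    """
    yr = records["admission_datetime"].dt.year
    if years is None:
        years = set(yr.unique())
    years = sorted(years)
    if not years:
        raise ValueError("years must be nonempty")
    counts = (
        pd.crosstab(records["hospital_id"], yr).reindex(columns=years, fill_value=0)
    )
    ok = (counts >= min_per_year).all(axis=1)
    dropped = sorted(counts.index[~ok])
    retained = records[~records["hospital_id"].isin(dropped)].copy()
    if dropped:
        logger.info("volume filter dropped %d hospital(s): %s", len(dropped), dropped)
    return retained, dropped


def _vitals_lookup(vitals: pd.DataFrame) -> dict:
    out = {}
    if vitals is None or vitals.empty:
        return out
    for row in vitals.itertuples(index=False):
        contrib = getattr(row, "contributing_causes", "") or ""
        if not isinstance(contrib, str):
            contrib = ""
        dd = row.death_date
        if pd.isna(dd):
            continue
        out[row.patient_id] = (
            pd.Timestamp(dd).date(),
            getattr(row, "underlying_cause", None) or None,
            [c for c in contrib.split("|") if c],
        )
    return out


def build_episodes(
    records: pd.DataFrame,
    vitals: pd.DataFrame | None = None,
    max_gap_hours: float = 24.0,
    first_per_year: bool = True,
) -> list[EpisodeOfCare]:
    """Chain admissions into episodes of care and join death information.

    Consecutive stays of one patient with a discharge-to-admission gap of at
    most ``max_gap_hours`` (inclusive) form one episode.  Overlapping stays
    are a data error: the earlier stay's end is truncated to the later start,
    with a logged warning.  Death-during-stay is decided at date precision; a
    death dated on a stay's discharge day counts as in-hospital there, and a
    death dated on a transfer day is attributed to the later stay.
    """
    deaths = _vitals_lookup(vitals) if vitals is not None else {}
    rec = records.sort_values(
        ["patient_id", "admission_datetime"], kind="mergesort"
    ).reset_index(drop=True)
    gap_h = (
        rec["admission_datetime"]
        - rec.groupby("patient_id", sort=False)["discharge_datetime"].shift()
    ) / pd.Timedelta(hours=1)
    new_chain = gap_h.isna() | (gap_h > max_gap_hours)
    chain = (new_chain.groupby(rec["patient_id"], sort=False).cumsum() - 1).astype(int)

    episodes: list[EpisodeOfCare] = []
    years_seen: set[int] = set()

    def _finish(ep: EpisodeOfCare) -> None:
        year = ep.stays[0].start.year
        if first_per_year and year in years_seen:
            return  # first episode per patient per calendar year
        years_seen.add(year)
        if ep.patient_id in deaths:
            dd, under, contrib = deaths[ep.patient_id]
            ep.death_date = dd
            ep.underlying_cause = under
            ep.contributing_causes = contrib
            for i in reversed(range(len(ep.stays))):
                s = ep.stays[i]
                if s.start.date() <= dd <= s.end.date():
                    ep.death_in_hospital_stay = i
                    break
        episodes.append(ep)

    current: EpisodeOfCare | None = None
    for row, ci in zip(rec.itertuples(index=False), chain.to_numpy()):
        key = (row.patient_id, ci)
        if current is None or (current.patient_id, current._chain) != key:  # type: ignore[attr-defined]
            if current is not None:
                _finish(current)
            if current is None or current.patient_id != row.patient_id:
                years_seen = set()
            current = EpisodeOfCare(
                episode_id=f"E{row.patient_id}-{ci}",
                patient_id=row.patient_id,
                condition=row.condition,
                stays=[],
                age_years=float(row.age_years),
                sex=row.sex,
                stage=str(row.stage),
            )
            current._chain = ci  # type: ignore[attr-defined]
        start, end = row.admission_datetime, row.discharge_datetime
        if current.stays and start < current.stays[-1].end:
            logger.warning(
                "overlapping stays for patient %s: truncating %s -> %s",
                row.patient_id,
                current.stays[-1].end,
                start,
            )
            last = current.stays[-1]
            current.stays[-1] = HospitalStay(last.hospital_id, last.start, start)
        current.stays.append(HospitalStay(row.hospital_id, start, end))
    if current is not None:
        _finish(current)
    return episodes


# --- plain-text IO ----------------------------------------------------------

def episodes_to_frame(episodes: list[EpisodeOfCare]) -> pd.DataFrame:
    """One row per stay, episode-level fields repeated."""
    rows = []
    for ep in episodes:
        for i, s in enumerate(ep.stays):
            rows.append(
                {
                    "episode_id": ep.episode_id,
                    "patient_id": ep.patient_id,
                    "condition": ep.condition,
                    "stay_index": i,
                    "hospital_id": s.hospital_id,
                    "start": s.start,
                    "end": s.end,
                    "los_days": s.los_days,
                    "age_years": ep.age_years,
                    "sex": ep.sex,
                    "stage": ep.stage,
                    "death_date": ep.death_date,
                    "death_in_hospital_stay": (
                        ep.death_in_hospital_stay
                        if ep.death_in_hospital_stay is not None
                        else ""
                    ),
                    "underlying_cause": ep.underlying_cause or "",
                    "contributing_causes": "|".join(ep.contributing_causes),
                }
            )
    return pd.DataFrame(rows)


def frame_to_episodes(frame: pd.DataFrame) -> list[EpisodeOfCare]:
    frame = frame.sort_values(["episode_id", "stay_index"], kind="mergesort")
    episodes: list[EpisodeOfCare] = []
    current: EpisodeOfCare | None = None
    for r in frame.itertuples(index=False):
        if current is None or current.episode_id != r.episode_id:
            dd = r.death_date
            death_stay = r.death_in_hospital_stay
            contrib = r.contributing_causes if isinstance(r.contributing_causes, str) else ""
            under = r.underlying_cause if isinstance(r.underlying_cause, str) else None
            current = EpisodeOfCare(
                episode_id=r.episode_id,
                patient_id=r.patient_id,
                condition=r.condition,
                stays=[],
                age_years=float(r.age_years),
                sex=r.sex,
                stage=str(r.stage),
                death_date=None if pd.isna(dd) else pd.Timestamp(dd).date(),
                death_in_hospital_stay=(
                    int(death_stay) if str(death_stay) not in ("", "nan") else None
                ),
                underlying_cause=under or None,
                contributing_causes=[c for c in contrib.split("|") if c],
            )
            episodes.append(current)
        current.stays.append(
            HospitalStay(r.hospital_id, pd.Timestamp(r.start), pd.Timestamp(r.end))
        )
    return episodes


def write_episodes(
    out_dir: str | Path,
    episodes: list[EpisodeOfCare],
    exclusion_log: pd.DataFrame | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    episodes_to_frame(episodes).to_csv(
        out / "episodes.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S"
    )
    if exclusion_log is not None:
        exclusion_log.to_csv(out / "exclusions.csv", index=False)


def read_episodes(path: str | Path) -> list[EpisodeOfCare]:
    frame = pd.read_csv(
        Path(path),
        parse_dates=["start", "end", "death_date"],
        keep_default_na=False,
        na_values=[""],
    )
    return frame_to_episodes(frame)
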