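"""Shared fixtures and toy-data builders."""

from __future__ import annotations

import pandas as pd
import pytest

from hospmort.episode_builder import EpisodeOfCare, HospitalStay

BASE = pd.Timestamp("1998-03-01 00:00")


def make_episode(
    stays,
    death_day: float | None = None,
    death_stay="auto",
    age: float = 70.0,
    sex: str = "M",
    stage: str = "s1",
    condition: str = "AMI",
    episode_id: str = "E1",
    patient_id: str = "P1",
    underlying: str | None = None,
    contributing=(),
):
    """Build an episode from ``stays = [(hospital_id, start_day, end_day), ...]``.

    Day offsets are from the index admission; ``death_day`` is the (date-level)
    day offset of death.  ``death_stay='auto'`` locates the death inside the
    latest stay whose date range contains it, mirroring the episode builder.
    """
    slist = [
        HospitalStay(h, BASE + pd.Timedelta(days=a), BASE + pd.Timedelta(days=b))
        for h, a, b in stays
    ]
    death_date = None
    if death_day is not None:
        death_date = (BASE + pd.Timedelta(days=death_day)).date()
    ds = None
    if death_date is not None and death_stay == "auto":
        for i in reversed(range(len(slist))):
            if slist[i].start.date() <= death_date <= slist[i].end.date():
                ds = i
                break
    elif death_stay != "auto":
        ds = death_stay
    return EpisodeOfCare(
        episode_id=episode_id,
        patient_id=patient_id,
        condition=condition,
        stays=slist,
        age_years=age,
        sex=sex,
        stage=stage,
        death_date=death_date,
        death_in_hospital_stay=ds,
        underlying_cause=underlying,
        contributing_causes=list(contributing),
    )


def admission(
    patient="P1",
    hospital="A",
    adm="1998-03-01 00:00",
    dis="1998-03-04 00:00",
    condition="AMI",
    age=70.0,
    sex="M",
    stage="s1",
    admission_type="acute",
    dead_on_arrival=False,
    rehab_flag=False,
):
    return dict(
        patient_id=patient,
        hospital_id=hospital,
        condition=condition,
        admission_datetime=pd.Timestamp(adm),
        discharge_datetime=pd.Timestamp(dis),
        admission_type=admission_type,
        primary_dx="410",
        secondary_dx="",
        age_years=age,
        sex=sex,
        stage=stage,
        dead_on_arrival=dead_on_arrival,
        rehab_flag=rehab_flag,
    )


def admissions_frame(*rows) -> pd.DataFrame:
    return pd.DataFrame(list(rows))


@pytest.fixture
def small_sim_config():
    """Small but non-trivial simulated registry configuration (1 year)."""
    from hospmort.synthetic_registry import default_config

    return default_config(
        "AMI",
        seed=11,
        years=1,
        n_hospitals={"small": 8, "large": 4, "university": 2},
        patients_per_hospital_year={"small": 120.0, "large": 260.0, "university": 380.0},
    )
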