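"""Exclusion rules, volume filter and transfer-chain construction."""

import numpy as np
import pandas as pd
import pytest

from hospmort.episode_builder import (
    apply_exclusions,
    build_episodes,
    episodes_to_frame,
    filter_hospitals_by_volume,
    frame_to_episodes,
    study_years,
)
from tests.conftest import admission, admissions_frame


def _reasons(log):
    return dict(zip(log["record_index"], log["reason"]))


class TestApplyExclusions:
    @pytest.mark.parametrize(
        "condition,age,expect_retained",
        [
            ("AMI", 17.9, False),
            ("AMI", 18.0, True),  # rule excludes strictly < 18
            ("stroke", 17.0, False),
            ("stroke", 18.0, True),
            ("hip_fracture", 64.0, False),
            ("hip_fracture", 65.0, True),
        ],
    )
    def test_age_cutoffs_are_strict(self, condition, age, expect_retained):
        df = admissions_frame(admission(age=age, condition=condition))
        retained, log = apply_exclusions(df, condition)
        assert (len(retained) == 1) == expect_retained
        if not expect_retained:
            assert _reasons(log)[0] == "underage"

    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            (dict(dead_on_arrival=True), "dead_on_arrival"),
            (dict(admission_type="elective"), "non_acute"),
            (dict(rehab_flag=True), "rehab"),
            (dict(age=np.nan), "missing_data"),
            (dict(stage=None), "missing_data"),
        ],
    )
    def test_record_level_rules(self, kwargs, reason):
        df = admissions_frame(admission(**kwargs))
        retained, log = apply_exclusions(df, "AMI")
        assert retained.empty
        assert _reasons(log)[0] == reason

    def test_first_admission_per_calendar_year(self):
        """Two separated 1998 admissions plus one 1999: the second 1998 one is
        a readmission; the 1998 first and the 1999 one are retained."""
        df = admissions_frame(
            admission(adm="1998-02-01 08:00", dis="1998-02-05 08:00"),
            admission(adm="1998-07-01 08:00", dis="1998-07-04 08:00"),
            admission(adm="1999-03-01 08:00", dis="1999-03-05 08:00"),
        )
        retained, log = apply_exclusions(df, "AMI")
        assert len(retained) == 2
        assert _reasons(log)[1] == "readmission_same_year"
        assert log["retained"].tolist() == [True, False, True]

    def test_chained_readmission_is_kept_with_its_chain(self):
        """A stay starting 20 h after discharge belongs to the first chain and
        is retained, not dropped as a same-year readmission."""
        df = admissions_frame(
            admission(hospital="A", adm="1998-02-01 08:00", dis="1998-02-05 08:00"),
            admission(hospital="B", adm="1998-02-06 04:00", dis="1998-02-10 08:00"),
        )
        retained, _ = apply_exclusions(df, "AMI")
        assert len(retained) == 2

    def test_every_record_logged_once(self):
        rows = [admission(patient=f"P{i}", age=16 + i) for i in range(6)]
        df = admissions_frame(*rows)
        retained, log = apply_exclusions(df, "AMI")
        assert len(log) == len(df)
        assert log["retained"].sum() == len(retained)


class TestVolumeFilter:
    def _records(self, counts_by_hospital_year):
        rows = []
        i = 0
        for (h, year), c in counts_by_hospital_year.items():
            for _ in range(c):
                rows.append(
                    admission(
                        patient=f"P{i}",
                        hospital=h,
                        adm=f"{year}-06-01 08:00",
                        dis=f"{year}-06-03 08:00",
                    )
                )
                i += 1
        return admissions_frame(*rows)

    def test_one_bad_year_drops_hospital(self):
        counts = {("A", y): 25 for y in range(1997, 2001)}
        counts[("A", 2001)] = 19
        counts.update({("B", y): 20 for y in range(1997, 2002)})
        df = self._records(counts)
        retained, dropped = filter_hospitals_by_volume(df, 20, set(range(1997, 2002)))
        assert dropped == ["A"]
        assert set(retained["hospital_id"]) == {"B"}

    def test_boundary_exactly_min_retained(self):
        counts = {("A", y): 20 for y in range(1997, 2002)}
        df = self._records(counts)
        _, dropped = filter_hospitals_by_volume(df, 20, set(range(1997, 2002)))
        assert dropped == []

    def test_only_failing_hospital_removed(self):
        counts = {}
        for h, per_year in (("A", 30), ("B", 21), ("C", 5)):
            for y in range(1997, 2002):
                counts[(h, y)] = per_year
        df = self._records(counts)
        retained, dropped = filter_hospitals_by_volume(df, 20, set(range(1997, 2002)))
        # brute-force expectation: only C fails in at least one year
        assert dropped == ["C"]
        assert set(retained["hospital_id"]) == {"A", "B"}

    def test_missing_year_counts_as_zero(self):
        counts = {("A", y): 25 for y in (1997, 1998, 2000, 2001)}  # no 1999
        df = self._records(counts)
        _, dropped = filter_hospitals_by_volume(df, 20, set(range(1997, 2002)))
        assert dropped == ["A"]

    def test_study_years_ignores_spillover_transfer_stays(self):
        df = admissions_frame(
            admission(adm="1998-12-30 10:00", dis="1998-12-31 20:00"),
            admission(hospital="B", adm="1999-01-01 06:00", dis="1999-01-05 06:00"),
        )
        assert study_years(df) == {1998}


class TestBuildEpisodes:
    def test_gap_of_exactly_24h_chains(self):
        df = admissions_frame(
            admission(hospital="A", adm="1998-03-01 00:00", dis="1998-03-04 00:00"),
            admission(hospital="B", adm="1998-03-05 00:00", dis="1998-03-08 00:00"),
        )
        eps = build_episodes(df)
        assert len(eps) == 1 and len(eps[0].stays) == 2

    def test_gap_above_24h_splits(self):
        df = admissions_frame(
            admission(hospital="A", adm="1998-03-01 00:00", dis="1998-03-04 00:00"),
            admission(hospital="B", adm="1998-03-05 00:30", dis="1998-03-08 00:00"),
        )
        eps = build_episodes(df, first_per_year=False)
        assert len(eps) == 2
        # under the first-admission rule the later same-year episode is dropped
        eps_default = build_episodes(df)
        assert len(eps_default) == 1 and len(eps_default[0].stays) == 1

    def test_three_stay_chain(self):
        df = admissions_frame(
            admission(hospital="A", adm="1998-03-01 00:00", dis="1998-03-04 00:00"),
            admission(hospital="B", adm="1998-03-04 02:00", dis="1998-03-06 02:00"),
            admission(hospital="C", adm="1998-03-06 12:00", dis="1998-03-10 12:00"),
        )
        eps = build_episodes(df)
        assert len(eps) == 1
        assert eps[0].n_distinct_hospitals == 3
        assert [s.hospital_id for s in eps[0].stays] == ["A", "B", "C"]

    def test_same_hospital_chain_is_not_transferred(self):
        df = admissions_frame(
            admission(hospital="A", adm="1998-03-01 00:00", dis="1998-03-04 00:00"),
            admission(hospital="A", adm="1998-03-04 10:00", dis="1998-03-08 00:00"),
        )
        eps = build_episodes(df)
        assert len(eps) == 1
        assert not eps[0].transferred

    def test_overlapping_stays_truncated(self, caplog):
        df = admissions_frame(
            admission(hospital="A", adm="1998-03-01 00:00", dis="1998-03-06 00:00"),
            admission(hospital="B", adm="1998-03-04 00:00", dis="1998-03-08 00:00"),
        )
        with caplog.at_level("WARNING"):
            eps = build_episodes(df)
        assert len(eps) == 1
        assert eps[0].stays[0].end == pd.Timestamp("1998-03-04 00:00")
        assert eps[0].total_los_days() == pytest.approx(3 + 4)
        assert any("overlapping" in m for m in caplog.messages)

    def test_death_joined_and_located(self):
        df = admissions_frame(
            admission(hospital="A", adm="1998-03-01 08:00", dis="1998-03-05 08:00"),
        )
        vitals = pd.DataFrame(
            {
                "patient_id": ["P1"],
                "death_date": [pd.Timestamp("1998-03-05")],  # discharge day
                "underlying_cause": ["410"],
                "contributing_causes": [""],
            }
        )
        eps = build_episodes(df, vitals)
        assert eps[0].death_in_hospital_stay == 0  # discharge-day death is in-hospital
        eps[0].death_date is not None

    def test_out_of_hospital_death_not_located(self):
        df = admissions_frame(admission(dis="1998-03-05 08:00"))
        vitals = pd.DataFrame(
            {
                "patient_id": ["P1"],
                "death_date": [pd.Timestamp("1998-03-20")],
                "underlying_cause": ["410"],
                "contributing_causes": [""],
            }
        )
        eps = build_episodes(df, vitals)
        assert eps[0].death_in_hospital_stay is None

    def test_order_independence(self):
        rows = [
            admission(patient="P1", hospital="A", adm="1998-03-01 00:00", dis="1998-03-04 00:00"),
            admission(patient="P1", hospital="B", adm="1998-03-04 12:00", dis="1998-03-08 00:00"),
            admission(patient="P2", hospital="C", adm="1998-05-01 00:00", dis="1998-05-02 00:00"),
            admission(patient="P3", hospital="A", adm="1998-06-01 00:00", dis="1998-06-03 00:00"),
        ]
        base = episodes_to_frame(build_episodes(admissions_frame(*rows)))
        rng = np.random.default_rng(4)
        for _ in range(5):
            shuffled = admissions_frame(*[rows[i] for i in rng.permutation(len(rows))])
            got = episodes_to_frame(build_episodes(shuffled))
            pd.testing.assert_frame_equal(
                got.sort_values(["episode_id", "stay_index"]).reset_index(drop=True),
                base.sort_values(["episode_id", "stay_index"]).reset_index(drop=True),
            )

    def test_partition_reconciles_with_exclusion_log(self):
        rows = [
            admission(patient="P1", age=17.0),
            admission(patient="P2", hospital="A", adm="1998-03-01 00:00", dis="1998-03-04 00:00"),
            admission(patient="P2", hospital="B", adm="1998-03-04 12:00", dis="1998-03-08 00:00"),
            admission(patient="P3", admission_type="elective"),
            admission(patient="P4"),
        ]
        df = admissions_frame(*rows)
        retained, log = apply_exclusions(df, "AMI")
        eps = build_episodes(retained)
        n_stays = sum(len(e.stays) for e in eps)
        assert n_stays + (~log["retained"]).sum() == len(df)

    def test_idempotent_on_built_single_stay_episodes(self):
        df = admissions_frame(
            admission(patient="P1"), admission(patient="P2", hospital="B")
        )
        eps = build_episodes(df)
        frame = episodes_to_frame(eps)
        rebuilt = frame.rename(
            columns={"start": "admission_datetime", "end": "discharge_datetime"}
        )[["patient_id", "hospital_id", "condition", "admission_datetime",
           "discharge_datetime", "age_years", "sex", "stage"]]
        rebuilt["admission_type"] = "acute"
        eps2 = build_episodes(rebuilt)
        assert episodes_to_frame(eps2).drop(columns=["episode_id"]).equals(
            episodes_to_frame(eps).drop(columns=["episode_id"])
        )

    def test_frame_round_trip(self):
        df = admissions_frame(
            admission(hospital="A", adm="1998-03-01 00:00", dis="1998-03-04 00:00"),
            admission(hospital="B", adm="1998-03-04 12:00", dis="1998-03-08 00:00"),
        )
        vitals = pd.DataFrame(
            {
                "patient_id": ["P1"],
                "death_date": [pd.Timestamp("1998-03-07")],
                "underlying_cause": ["I21.1"],
                "contributing_causes": ["J18.9|N17.9"],
            }
        )
        eps = build_episodes(df, vitals)
        back = frame_to_episodes(episodes_to_frame(eps))
        assert len(back) == 1
        assert back[0].death_in_hospital_stay == eps[0].death_in_hospital_stay
        assert back[0].contributing_causes == ["J18.9", "N17.9"]
        assert [s.hospital_id for s in back[0].stays] == ["A", "B"]
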