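"""Counting rules: time-fraction weights, the three measures, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hospmort.episode_builder import apply_exclusions, build_episodes
from hospmort.mortality_measures import (
    compute_ih30d,
    compute_s30d,
    compute_w30d,
    crude_mortality,
    stay_weights,
    summarize_cohort,
)
from hospmort.synthetic_registry import (
    default_config,
    generate_cohort,
    generate_hospitals,
)
from tests.conftest import make_episode


class TestStayWeights:
    def test_worked_example_survivor(self):
        """10 days at hospital 1, transfer, discharged from hospital 2 on day
        25: weights 10/25 and 15/25."""
        ep = make_episode([("h1", 0, 10), ("h2", 10, 25)])
        assert stay_weights(ep) == pytest.approx({"h1": 0.4, "h2": 0.6})

    def test_worked_example_truncated_at_window(self):
        ep = make_episode([("h1", 0, 10), ("h2", 10, 31)])
        assert stay_weights(ep) == pytest.approx({"h1": 10 / 30, "h2": 20 / 30})

    def test_single_hospital_gets_full_weight(self):
        ep = make_episode([("h1", 0, 3.7)])
        assert stay_weights(ep) == {"h1": 1.0}

    def test_same_hospital_stays_pooled(self):
        ep = make_episode([("h1", 0, 5), ("h2", 5, 10), ("h1", 10.5, 15.5)])
        w = stay_weights(ep)
        assert w == pytest.approx({"h1": 10 / 15, "h2": 5 / 15})

    def test_zero_duration_degenerate_equal_weights(self):
        ep = make_episode([("h1", 0, 0), ("h2", 0.5, 0.5)])
        w = stay_weights(ep)
        assert w == pytest.approx({"h1": 0.5, "h2": 0.5})

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["h1", "h2", "h3"]),
                st.floats(0.05, 25.0),
                st.floats(0.0, 0.9),
            ),
            min_size=1,
            max_size=4,
        )
    )
    def test_weights_sum_to_one(self, stay_spec):
        t = 0.0
        stays = []
        for h, los, gap in stay_spec:
            stays.append((h, t + gap, t + gap + los))
            t += gap + los
        ep = make_episode(stays)
        assert sum(stay_weights(ep).values()) == pytest.approx(1.0, abs=1e-9)


class TestW30D:
    def test_day_31_death_counts_alive_at_both_hospitals(self):
        ep = make_episode([("h1", 0, 10), ("h2", 10, 31)], death_day=31)
        obs = compute_w30d([ep]).observations
        assert (obs["outcome"] == 0).all()
        assert sorted(obs["weight"]) == pytest.approx([10 / 30, 20 / 30])

    def test_day_30_death_counts_dead(self):
        ep = make_episode([("h1", 0, 5)], death_day=30)
        obs = compute_w30d([ep]).observations
        assert obs["outcome"].tolist() == [1]

    def test_out_of_hospital_death_counts(self):
        ep = make_episode([("h1", 0, 5)], death_day=12)
        obs = compute_w30d([ep]).observations
        assert obs["outcome"].tolist() == [1] and obs["weight"].tolist() == [1.0]

    def test_no_death_record_is_survivor(self):
        ep = make_episode([("h1", 0, 5)])
        assert compute_w30d([ep]).observations["outcome"].tolist() == [0]

    def test_all_hospitals_share_episode_outcome(self):
        ep = make_episode([("h1", 0, 10), ("h2", 10, 20)], death_day=25)
        obs = compute_w30d([ep]).observations
        assert (obs["outcome"] == 1).all()


class TestS30D:
    def test_transferred_patient_excluded_entirely(self):
        ep = make_episode([("h1", 0, 10), ("h2", 10, 25)])
        assert len(compute_s30d([ep])) == 0

    def test_single_hospital_out_of_hospital_death(self):
        ep = make_episode([("h1", 0, 8)], death_day=20)
        obs = compute_s30d([ep]).observations
        assert obs["outcome"].tolist() == [1] and obs["weight"].tolist() == [1.0]

    def test_single_hospital_survivor(self):
        ep = make_episode([("h1", 0, 8)])
        obs = compute_s30d([ep]).observations
        assert obs["outcome"].tolist() == [0] and obs["weight"].tolist() == [1.0]


class TestIH30D:
    def test_death_day_21_of_second_admission_counts_there_only(self):
        """Transfer on day 10, death on day 21 of the second hospital's stay:
        hospital 1 counts a survivor, hospital 2 a death."""
        ep = make_episode([("h1", 0, 10), ("h2", 10, 31)], death_day=31)
        obs = compute_ih30d([ep]).observations.set_index("hospital_id")
        assert obs.loc["h1", "outcome"] == 0
        assert obs.loc["h2", "outcome"] == 1
        assert (obs["weight"] == 1.0).all()

    def test_out_of_hospital_death_counts_nowhere(self):
        ep = make_episode([("h1", 0, 2), ("h2", 2, 4)], death_day=5)
        obs = compute_ih30d([ep]).observations
        assert (obs["outcome"] == 0).all()

    def test_in_hospital_death_beyond_30_days_of_that_admission(self):
        ep = make_episode([("h1", 0, 40)], death_day=35)
        obs = compute_ih30d([ep]).observations
        assert obs["outcome"].tolist() == [0]


class TestCountIdentities:
    def _episodes(self):
        return [
            make_episode([("h1", 0, 10), ("h2", 10, 25)], episode_id="E1"),
            make_episode([("h1", 0, 5)], death_day=3, episode_id="E2"),
            make_episode([("h2", 0, 4), ("h3", 4.2, 9)], death_day=8, episode_id="E3"),
            make_episode([("h3", 0, 7)], episode_id="E4"),
        ]

    def test_observation_counts(self):
        eps = self._episodes()
        n_hosp = sum(e.n_distinct_hospitals for e in eps)
        assert len(compute_w30d(eps)) == n_hosp
        assert len(compute_ih30d(eps)) == n_hosp
        assert len(compute_s30d(eps)) == sum(not e.transferred for e in eps)

    def test_w30d_overall_equals_episode_death_fraction(self):
        eps = self._episodes()
        _, overall = crude_mortality(compute_w30d(eps))
        deaths = sum(
            e.death_date is not None and e.days_to_death() <= 30 for e in eps
        )
        assert overall == pytest.approx(deaths / len(eps))

    def test_ih30d_never_counts_out_of_hospital_deaths(self):
        eps = self._episodes() + [make_episode([("h1", 0, 3)], death_day=20, episode_id="E5")]
        obs = compute_ih30d(eps).observations
        in_hosp_deaths = sum(e.death_in_hospital_stay is not None for e in eps)
        assert obs["outcome"].sum() <= in_hosp_deaths


class TestCrude:
    def test_simple_proportion(self):
        eps = [
            make_episode([("h1", 0, 5)], death_day=(2 if i < 2 else None), episode_id=f"E{i}")
            for i in range(10)
        ]
        per_hosp, overall = crude_mortality(compute_w30d(eps))
        assert overall == pytest.approx(0.2)
        assert per_hosp.set_index("hospital_id").loc["h1", "crude_mortality"] == pytest.approx(0.2)

    def test_weighted_survivor_only_hospital(self):
        ep = make_episode([("h1", 0, 10), ("h2", 10, 25)])
        per_hosp, _ = crude_mortality(compute_w30d([ep]))
        row = per_hosp.set_index("hospital_id")
        assert row.loc["h1", "crude_mortality"] == 0.0
        assert row.loc["h1", "effective_n"] == pytest.approx(0.4)


class TestEquivalenceWithoutTransfers:
    def test_measures_coincide_on_transfer_free_in_hospital_deaths(self):
        """With no transfers and every death in hospital within 30 days, the
        three counting rules produce identical observation tables."""
        cfg = default_config(
            "AMI",
            seed=21,
            years=1,
            n_hospitals={"small": 6, "large": 3, "university": 1},
            patients_per_hospital_year={"small": 60.0, "large": 140.0, "university": 200.0},
            transfer_probability=0.0,
            out_of_hospital_death_share=0.0,
            late_death_shares=(0.0, 0.0),
        )
        hs = generate_hospitals(cfg)
        adm, vit, _ = generate_cohort(cfg, hs)
        ret, _ = apply_exclusions(adm, "AMI")
        eps = build_episodes(ret, vit)
        tables = {
            m.measure_id: m.observations.drop(columns=["measure_id"]).reset_index(drop=True)
            for m in (compute_w30d(eps), compute_s30d(eps), compute_ih30d(eps))
        }
        pd.testing.assert_frame_equal(tables["W30D"], tables["S30D"])
        pd.testing.assert_frame_equal(tables["W30D"], tables["IH30D"])


class TestSummarize:
    def test_interval_counts_toy(self):
        eps = [
            make_episode([("h1", 0, 5)], death_day=10, episode_id="E1"),
            make_episode([("h1", 0, 5)], death_day=40, episode_id="E2"),
            make_episode([("h1", 0, 5)], death_day=100, episode_id="E3"),
            make_episode([("h1", 0, 5)], episode_id="E4"),
            make_episode([("h1", 0, 5)], episode_id="E5"),
        ]
        s = summarize_cohort(eps)
        by = s["deaths_by_interval"]
        assert (by["le30"]["n"], by["d31_90"]["n"], by["d91_365"]["n"]) == (1, 1, 1)
        assert by["alive_gt_1y"]["n"] == 2

    def test_place_of_death_classification(self):
        eps = [
            make_episode([("h1", 0, 10)], death_day=5, episode_id="E1"),
            make_episode([("h1", 0, 4), ("h2", 4, 20)], death_day=15, episode_id="E2"),
            make_episode([("h1", 0, 4)], death_day=25, episode_id="E3"),
        ]
        s = summarize_cohort(eps)
        p = s["place_of_death_30d"]
        assert p["during_first_admission"]["n"] == 1
        assert p["different_hospital"]["n"] == 1
        assert p["out_of_hospital"]["n"] == 1

    def test_cause_match_from_underlying_or_contributing(self):
        dead = make_episode([("h1", 0, 5)], death_day=4, underlying="I21.1")
        contrib = make_episode(
            [("h1", 0, 5)], death_day=4, underlying="J18.9", contributing=["410.1"],
            episode_id="E2",
        )
        nomatch = make_episode(
            [("h1", 0, 5)], death_day=4, underlying="J18.9", episode_id="E3"
        )
        s = summarize_cohort([dead, contrib, nomatch])
        assert s["cause_match_30d"]["n"] == 2

    def test_simulated_cause_match_share(self):
        cfg = default_config(
            "AMI",
            seed=13,
            years=1,
            n_hospitals={"small": 6, "large": 3, "university": 1},
            patients_per_hospital_year={"small": 300.0, "large": 700.0, "university": 1000.0},
            cause_match_probability=0.9,
        )
        hs = generate_hospitals(cfg)
        adm, vit, _ = generate_cohort(cfg, hs)
        ret, _ = apply_exclusions(adm, "AMI")
        eps = build_episodes(ret, vit)
        s = summarize_cohort(eps)
        n30 = s["deaths_by_interval"]["le30"]["n"]
        share = s["cause_match_30d"]["n"] / n30
        se = np.sqrt(0.9 * 0.1 / n30)
        assert abs(share - 0.9) < 3.5 * se
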