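import numpy as np
import pandas as pd
import pytest

from amimap import (
    aggregate_events,
    apply_28day_rule,
    exclude_short_stays,
    filter_eligible,
    link_events,
    link_in_hospital_deaths,
    merge_same_day_episodes,
)
from amimap._common import LinkageError
from conftest import death_frame, hosp_frame, random_person_records
from linkage_oracle import brute_force_event_count


class TestEligibility:
    @pytest.mark.parametrize(
        "dx,age,kept",
        [
            ("I21.4", 60, True),
            ("I22.9", 35, True),
            ("I25.1", 60, False),  # not I21-I22
            ("I21.0", 34, False),  # under age
            ("garbage", 60, False),  # malformed
        ],
    )
    def test_hospital_rules(self, dx, age, kept):
        h = hosp_frame([("p1", "2010-01-01", "2010-01-05", "alive", dx, age)])
        fh, _, drops = filter_eligible(h, death_frame([]))
        assert (len(fh) == 1) is kept

    def test_drop_reasons_counted(self):
        h = hosp_frame(
            [
                ("p1", "2010-01-01", "2010-01-05", "alive", "I21.0", 60),
                ("p2", "2010-01-01", "2010-01-05", "alive", "E11.9", 60),
                ("p3", "2010-01-01", "2010-01-05", "alive", "??", 60),
                ("p4", "2010-01-01", "2010-01-05", "alive", "I22.0", 30),
            ]
        )
        d = death_frame([("p5", "2010-02-01", "out_of_hospital", "I60.1", 70)])
        fh, fd, drops = filter_eligible(h, d)
        assert len(fh) == 1 and len(fd) == 0
        assert drops["hospital_not_i21_i22"] == 1
        assert drops["hospital_malformed_code"] == 1
        assert drops["hospital_under_age"] == 1
        assert drops["death_not_i21_i22"] == 1


class TestSameDayMerge:
    def test_chain_collapses_with_summed_los(self):
        h = hosp_frame(
            [
                ("p1", "2010-01-01", "2010-01-05"),
                ("p1", "2010-01-05", "2010-01-09"),
            ]
        )
        ep = merge_same_day_episodes(h)
        assert len(ep) == 1
        row = ep.iloc[0]
        assert row["onset_date"] == pd.Timestamp("2010-01-01")
        assert row["end_date"] == pd.Timestamp("2010-01-09")
        assert row["total_los"] == 8
        assert not row["fatal"]

    def test_gap_keeps_two_episodes(self):
        h = hosp_frame(
            [("p1", "2010-01-01", "2010-01-05"), ("p1", "2010-01-07", "2010-01-09")]
        )
        assert len(merge_same_day_episodes(h)) == 2

    def test_single_stay_identity(self):
        h = hosp_frame([("p1", "2010-01-01", "2010-01-04", "died")])
        ep = merge_same_day_episodes(h)
        assert len(ep) == 1
        assert ep.iloc[0]["total_los"] == 3 and ep.iloc[0]["fatal"]

    def test_overlapping_stays_merged_and_flagged(self):
        h = hosp_frame(
            [("p1", "2010-01-01", "2010-01-10"), ("p1", "2010-01-04", "2010-01-06")]
        )
        ep = merge_same_day_episodes(h)
        assert len(ep) == 1 and ep.iloc[0]["overlap"]


class TestShortStayExclusion:
    def test_isolated_one_day_stay_excluded(self):
        ep = merge_same_day_episodes(hosp_frame([("p1", "2010-01-01", "2010-01-02")]))
        out, n = exclude_short_stays(ep, death_frame([]))
        assert len(out) == 0 and n == 1

    def test_same_day_death_keeps_stay(self):
        ep = merge_same_day_episodes(hosp_frame([("p1", "2010-01-01", "2010-01-02")]))
        out, n = exclude_short_stays(ep, death_frame([("p1", "2010-01-02")]))
        assert len(out) == 1 and n == 0

    def test_chained_short_stay_kept_via_total_los(self):
        # a 1-day stay that chained into a same-day readmission: episode los > 1
        h = hosp_frame(
            [("p1", "2010-01-01", "2010-01-02"), ("p1", "2010-01-02", "2010-01-06")]
        )
        ep = merge_same_day_episodes(h)
        assert ep.iloc[0]["total_los"] == 5
        out, n = exclude_short_stays(ep, death_frame([]))
        assert len(out) == 1 and n == 0

    def test_chained_pair_kept_even_when_summed_los_is_short(self):
        # two same-day-chained records totalling <=1 day: had a readmission, kept
        h = hosp_frame(
            [("p1", "2010-01-01", "2010-01-01"), ("p1", "2010-01-01", "2010-01-02")]
        )
        ep = merge_same_day_episodes(h)
        out, n = exclude_short_stays(ep, death_frame([]))
        assert len(out) == 1 and n == 0


class TestDeathLinkage:
    def test_in_window_death_absorbed(self):
        ep = merge_same_day_episodes(
            hosp_frame([("p1", "2010-01-01", "2010-01-09", "died")])
        )
        out, n_abs, n_amb = link_in_hospital_deaths(ep, death_frame([("p1", "2010-01-09")]))
        assert len(out) == 1 and n_abs == 1 and n_amb == 0
        assert out.iloc[0]["fatal"] and out.iloc[0]["source"] == "hospital"

    def test_unmatched_death_becomes_event(self):
        out, n_abs, _ = link_in_hospital_deaths(
            merge_same_day_episodes(hosp_frame([])),
            death_frame([("p9", "2010-03-01", "out_of_hospital")]),
        )
        assert len(out) == 1 and n_abs == 0
        assert out.iloc[0]["source"] == "death_only" and out.iloc[0]["fatal"]

    def test_late_death_separate_then_merged_by_28day_rule(self):
        ep = merge_same_day_episodes(hosp_frame([("p1", "2010-01-01", "2010-01-09")]))
        out, n_abs, _ = link_in_hospital_deaths(ep, death_frame([("p1", "2010-01-20")]))
        assert len(out) == 2 and n_abs == 0  # two episodes at this stage
        events, collapsed = apply_28day_rule(out)
        assert len(events) == 1 and collapsed == 1
        assert events.iloc[0]["fatal"]


class TestTwentyEightDayRule:
    @pytest.mark.parametrize(
        "onset_days,expected",
        [
            ([0, 20, 40], 2),  # 20 merges into anchor 0; 40 opens a new event
            ([0, 29], 2),  # boundary: 29 > 28
            ([0, 28], 1),  # boundary: 28 merges
            ([0], 1),
            ([0, 10, 20, 28], 1),
            ([0, 28, 56], 2),  # anchored at 0, then at 56 (not rolling)
        ],
    )
    def test_anchored_collapse(self, onset_days, expected):
        base = pd.Timestamp("2010-01-01")
        rows = [
            ("p1", str((base + pd.Timedelta(days=d)).date()),
             str((base + pd.Timedelta(days=d + 2)).date()))
            for d in onset_days
        ]
        ep = merge_same_day_episodes(hosp_frame(rows))
        events, collapsed = apply_28day_rule(ep)
        assert len(events) == expected
        assert collapsed == len(onset_days) - expected

    def test_window_monotonicity(self):
        """A wider window can never produce more events."""
        rng = np.random.default_rng(77)
        h_rows, d_rows = [], []
        for i in range(200):
            h, d = random_person_records(rng, f"p{i}")
            h_rows += h
            d_rows += d
        hosp, dths = hosp_frame(h_rows), death_frame(d_rows)
        counts = [
            link_events(hosp, dths, window_days=w).audit.n_final_events
            for w in (0, 7, 28, 56, 365)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_idempotence_on_own_output(self):
        """Re-linking the linked events (re-embedded as records) is a no-op."""
        rng = np.random.default_rng(42)
        h_rows, d_rows = [], []
        for i in range(300):
            h, d = random_person_records(rng, f"p{i}")
            h_rows += h
            d_rows += d
        first = link_events(hosp_frame(h_rows), death_frame(d_rows))
        ev = first.events
        # re-embed: each event becomes a single >1-day stay, fatal ones died
        re_h = hosp_frame(
            [
                (r.person_id, str(pd.Timestamp(r.onset_date).date()),
                 str((pd.Timestamp(r.onset_date) + pd.Timedelta(days=2)).date()),
                 "died" if r.fatal else "alive", "I21.0", r.age)
                for r in ev.itertuples()
            ]
        )
        second = link_events(re_h, death_frame([]))
        a = first.events[["person_id", "onset_date", "fatal"]].reset_index(drop=True)
        b = second.events[["person_id", "onset_date", "fatal"]].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestBruteForceAgreement:
    def test_pipeline_matches_oracle_on_random_cases(self):
        rng = np.random.default_rng(2024)
        n_cases = 800
        h_rows, d_rows, expected = [], [], {}
        for i in range(n_cases):
            pid = f"c{i:05d}"
            h, d = random_person_records(rng, pid)
            h_rows += h
            d_rows += d
            expected[pid] = brute_force_event_count(h, d)
        res = link_events(hosp_frame(h_rows), death_frame(d_rows))
        got = res.events.groupby("person_id").size().to_dict()
        for pid, want in expected.items():
            assert got.get(pid, 0) == want, f"mismatch for {pid}"


class TestAggregation:
    def test_zero_events_full_zero_grid(self):
        counts = aggregate_events(
            pd.DataFrame(columns=["person_id", "onset_date", "fatal", "township_id", "age", "sex"]),
            ["T001", "T002"],
        )
        assert counts["count"].sum() == 0
        assert len(counts) == 2 * 2 * 4 * 4

    def test_boundary_year_period_assignment(self):
        ev = pd.DataFrame(
            {
                "person_id": ["a", "b"],
                "onset_date": [pd.Timestamp("2009-12-31"), pd.Timestamp("2010-01-01")],
                "fatal": [False, False],
                "township_id": ["T001", "T001"],
                "age": [60, 60],
                "sex": ["male", "male"],
            }
        )
        counts = aggregate_events(ev, ["T001"])
        by_period = counts.groupby("period")["count"].sum()
        assert by_period["2007-2009"] == 1 and by_period["2010-2012"] == 1

    def test_unknown_township_raises(self):
        ev = pd.DataFrame(
            {
                "person_id": ["a"],
                "onset_date": [pd.Timestamp("2010-06-01")],
                "fatal": [False],
                "township_id": ["T999"],
                "age": [60],
                "sex": ["male"],
            }
        )
        with pytest.raises(LinkageError, match="T999"):
            aggregate_events(ev, ["T001"])

    def test_synthetic_counts_match_ground_truth(self, tiny_city):
        res = link_events(tiny_city.hospital, tiny_city.deaths)
        counts = aggregate_events(res.events, tiny_city.map.townships)
        m = counts.merge(
            tiny_city.truth.counts, on=["township_id", "sex", "age_group", "period"]
        )
        assert (m["count"] == m["true_unique_event_count"]).all()
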