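import numpy as np
import pandas as pd
import pytest

from overuse_pipeline import (
    build_episodes,
    detect_dose_dumping,
    extract_window,
    extract_windows,
    highest_use_summary,
    preexacerbation_overuse_fraction,
    profile_medians,
    select_window_episodes,
)

from conftest import day, make_days, make_participants
from oracles import brute_force_dump_intervals


def _ocs(rows):
    return pd.DataFrame(
        [(pid, day(s), day(e)) for pid, s, e in rows],
        columns=["participant_id", "start_date", "end_date"],
    )


class TestBuildEpisodes:
    def test_single_course_anchors_day0(self):
        eps = build_episodes(_ocs([("P1", 10, 13)]))
        assert len(eps) == 1
        assert eps["day0"].iloc[0] == day(10)
        assert eps["therapy_days"].iloc[0] == 4

    def test_courses_with_short_gap_merge(self):
        eps = build_episodes(_ocs([("P1", 10, 12), ("P1", 15, 17)]))
        assert len(eps) == 1
        assert eps["day0"].iloc[0] == day(10)
        assert eps["n_courses"].iloc[0] == 2

    def test_courses_separated_by_seven_days_stay_separate(self):
        eps = build_episodes(_ocs([("P1", 10, 12), ("P1", 25, 27)]))
        assert len(eps) == 2

    def test_two_day_course_is_not_an_episode(self):
        eps = build_episodes(_ocs([("P1", 10, 11)]))
        assert len(eps) == 0

    def test_order_invariant_and_idempotent(self):
        rows = [("P1", 30, 33), ("P1", 10, 12), ("P2", 5, 9), ("P1", 15, 17)]
        a = build_episodes(_ocs(rows))
        b = build_episodes(_ocs(rows[::-1]))
        pd.testing.assert_frame_equal(
            a.sort_values(["participant_id", "day0"]).reset_index(drop=True),
            b.sort_values(["participant_id", "day0"]).reset_index(drop=True),
        )

    def test_overlapping_courses_merge_with_warning(self):
        with pytest.warns(UserWarning, match="overlapping"):
            eps = build_episodes(_ocs([("P1", 10, 14), ("P1", 12, 16)]))
        assert len(eps) == 1
        assert eps["therapy_days"].iloc[0] == 7


class TestSelectWindowEpisodes:
    def test_single_episode_included(self):
        eps = select_window_episodes(build_episodes(_ocs([("P1", 10, 13)])))
        assert eps["included_in_window_analysis"].all()

    def test_repeat_within_28_days_excluded_but_still_counts(self):
        eps = build_episodes(_ocs([("P1", 10, 12), ("P1", 30, 32), ("P1", 70, 72)]))
        out = select_window_episodes(eps)
        assert len(out) == 3  # still three exacerbation events
        assert out["included_in_window_analysis"].tolist() == [True, False, True]
        assert out["exclusion_reason"].tolist() == ["", "overlap_28d", ""]

    def test_no_monitor_data_exclusion(self):
        eps = build_episodes(_ocs([("P1", 10, 12), ("P2", 10, 12)]))
        has_data = pd.Series([False, True], index=eps.index)
        out = select_window_episodes(eps, has_monitor_data=has_data)
        assert out.set_index("participant_id")["exclusion_reason"].to_dict() == {
            "P1": "no_monitor_data", "P2": "",
        }


class TestExtractWindow:
    def test_full_window_has_29_offsets(self):
        days = make_days("P1", {}, n_days=60)
        win = extract_window(day(20), days)
        assert len(win) == 29
        assert win.notna().all().all()

    def test_truncation_at_monitoring_start(self):
        days = make_days("P1", {}, n_days=60)
        win = extract_window(day(5), days)
        assert win.loc[-14:-6].isna().all().all()
        assert win.loc[-5:].notna().all().all()

    def test_constant_use_gives_flat_profile(self):
        days = make_days("P1", {n: 4 for n in range(60)}, n_days=60)
        win = extract_window(day(20), days)
        assert (win["bud_form_actuations"] == 4).all()


class TestProfileMedians:
    def _profiles(self, values_by_episode):
        rows = []
        for i, v in enumerate(values_by_episode):
            rows.append(
                {"participant_id": f"P{i}", "day0": day(20), "offset": 0,
                 "bud_form_actuations": v, "salbutamol_actuations": np.nan}
            )
        windows = pd.DataFrame(rows)
        parts = make_participants([f"P{i}" for i in range(len(values_by_episode))])
        return profile_medians(windows, parts)

    def test_median_and_iqr_of_three_values(self):
        out = self._profiles([2, 4, 6]).set_index("medication").loc["BUD_FORM"]
        assert out["median"] == 4
        assert out["q1"] == 3.0 and out["q3"] == 5.0  # linear-interpolated quartiles
        assert out["n"] == 3

    def test_singleton(self):
        out = self._profiles([5]).set_index("medication").loc["BUD_FORM"]
        assert out["median"] == out["q1"] == out["q3"] == 5

    def test_offsets_without_data_absent(self):
        out = self._profiles([np.nan])
        assert len(out) == 0


class TestDoseDumping:
    def _events(self, times):
        return pd.DataFrame(
            {
                "participant_id": "P1",
                "medication": "SALBUTAMOL",
                "timestamp": [day(3) + pd.Timedelta(seconds=s) for s in times],
            }
        )

    def test_hundred_actuations_in_ten_minutes_flagged_once(self):
        ev = self._events(np.linspace(0, 600, 100))
        flags = detect_dose_dumping(ev)
        assert len(flags) == 1
        assert flags["actuation_count"].iloc[0] == 100

    def test_ninety_nine_actuations_not_flagged(self):
        ev = self._events(np.linspace(0, 600, 99))
        assert len(detect_dose_dumping(ev)) == 0

    def test_hundred_spread_over_three_hours_one_minute_not_flagged(self):
        ev = self._events(np.linspace(0, 3 * 3600 + 60, 100))
        assert len(detect_dose_dumping(ev)) == 0

    def test_matches_brute_force_pair_scan_on_random_fixtures(self):
        rng = np.random.default_rng(99)
        for trial in range(40):
            n = int(rng.integers(80, 140))
            # cluster events within ~4 hours so windows straddle the cut
            secs = np.sort(rng.integers(0, 4 * 3600, size=n))
            ev = self._events(secs)
            got = detect_dose_dumping(ev)
            expected = brute_force_dump_intervals(
                ev["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64)
            )
            assert len(got) == len(expected), (trial, n)
            for (_, row), (s, e, c) in zip(got.iterrows(), expected):
                assert row["window_start"].value == s
                assert row["window_end"].value == e
                assert row["actuation_count"] == c


class TestPreexacerbationFraction:
    def _outcomes(self, pid_day_unrev):
        return pd.DataFrame(
            [
                {"participant_id": pid, "date": day(d), "level": "HIGH",
                 "reviewed_within_48h": False, "in_standdown": not u,
                 "counted_as_unreviewed": u}
                for pid, d, u in pid_day_unrev
            ]
        )

    def test_small_worked_example(self):
        # one included episode at day 40; high days at -3, -1 (pre) and +5, +40 (not pre)
        eps = pd.DataFrame(
            {"participant_id": ["P1"], "day0": [day(40)],
             "included_in_window_analysis": [True]}
        )
        outcomes = self._outcomes(
            [("P1", 37, True), ("P1", 39, False), ("P1", 45, True), ("P1", 80, True)]
        )
        res = preexacerbation_overuse_fraction(eps, outcomes, "HIGH")
        assert res["n_pre"] == 2 and res["n_total"] == 4
        assert res["pct_pre_of_total"] == 50
        assert res["n_pre_unreviewed"] == 1
        assert res["pct_pre_unreviewed"] == 50

    def test_zero_episodes(self):
        eps = pd.DataFrame(
            columns=["participant_id", "day0", "included_in_window_analysis"]
        )
        outcomes = self._outcomes([("P1", 5, True)])
        res = preexacerbation_overuse_fraction(eps, outcomes, "HIGH")
        assert res["n_pre"] == 0 and res["pct_pre_of_total"] == 0
        assert res["pct_pre_unreviewed"] == 0


class TestHighestUseSummary:
    def _windows(self, sal_by_offset, bud_by_offset=None, pid="P1"):
        rows = []
        for off in range(-14, 15):
            rows.append(
                {"participant_id": pid, "day0": day(30), "offset": off,
                 "bud_form_actuations": (bud_by_offset or {}).get(off, 0),
                 "salbutamol_actuations": sal_by_offset.get(off, 0)}
            )
        return pd.DataFrame(rows)

    def test_max_of_hand_built_window(self):
        win = self._windows({-3: 18, -1: 7, 2: 25})
        res = highest_use_summary(win, "SALBUTAMOL")
        assert res["pre"]["median"] == 18 and res["pre"]["range"] == (18, 18)
        assert res["post"]["median"] == 25

    def test_all_zero_window_max_zero(self):
        res = highest_use_summary(self._windows({}), "SALBUTAMOL")
        assert res["pre"]["median"] == 0 and res["post"]["median"] == 0

    def test_companion_counts_on_max_day(self):
        win = self._windows({-3: 18, -2: 18}, bud_by_offset={-3: 9, -2: 2})
        res = highest_use_summary(win, "SALBUTAMOL", companion="BUD_FORM")
        # ties resolve to the earliest offset, so the companion count is 9
        assert res["pre"]["companion_median"] == 9
        assert res["pre"]["n_companion_gt8"] == 1
        assert res["pre"]["n_companion_zero"] == 0
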