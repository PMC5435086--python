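import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from overuse_pipeline import (
    ThresholdConfig,
    classify_day,
    classify_days,
    count_overuse_days,
)

from conftest import day, make_participants


@pytest.mark.parametrize(
    "bud, sal, arm, expected",
    [
        (13, 0, "SMART", "HIGH"),       # just over the >12 total cut-off
        (12, 0, "SMART", "NONE"),       # strict inequality at the boundary
        (17, 0, "SMART", "MARKED"),
        (21, 0, "SMART", "EXTREME"),
        (0, 17, "STANDARD", "HIGH"),
        (0, 16, "STANDARD", "NONE"),
        (0, 33, "STANDARD", "EXTREME"),
        # Standard-arm budesonide/formoterol reliever use is deliberately ignored
        (30, 10, "STANDARD", "NONE"),
        (0, 0, "SMART", "NONE"),
    ],
)
def test_regimen_specific_thresholds(bud, sal, arm, expected):
    assert classify_day(bud, sal, arm) == expected


def test_flags_nest_and_level_is_highest():
    df = pd.DataFrame(
        {
            "participant_id": "P1",
            "date": [day(i) for i in range(3)],
            "bud_form_actuations": [13, 17, 21],
            "salbutamol_actuations": 0,
        }
    )
    out = classify_days(df, make_participants(["P1"], arm="SMART"))
    assert out["high"].tolist() == [True, True, True]
    assert out["marked"].tolist() == [False, True, True]
    assert out["extreme"].tolist() == [False, False, True]
    assert out["overuse_level"].tolist() == ["HIGH", "MARKED", "EXTREME"]


def test_smart_excess_mode_equals_total_mode():
    cfg_total = ThresholdConfig(smart_mode="total")
    cfg_excess = ThresholdConfig(smart_mode="excess")
    for bud in range(0, 30):
        assert classify_day(bud, 0, "SMART", cfg_total) == \
            classify_day(bud, 0, "SMART", cfg_excess)


def test_threshold_config_requires_increasing_cutoffs():
    with pytest.raises(ValueError):
        ThresholdConfig(smart_total_thresholds=(16, 12, 20))


class TestCountOveruseDays:
    def _classified(self):
        # five days: H, H+M, none, H+M+E, none
        df = pd.DataFrame(
            {
                "participant_id": "P1",
                "date": [day(i) for i in range(5)],
                "bud_form_actuations": [13, 17, 2, 25, 0],
                "salbutamol_actuations": 0,
            }
        )
        return classify_days(df, make_participants(["P1"], arm="SMART"))

    def test_counts_per_level(self):
        cl = self._classified()
        assert count_overuse_days(cl, "HIGH")["P1"] == 3
        assert count_overuse_days(cl, "MARKED")["P1"] == 2
        assert count_overuse_days(cl, "EXTREME")["P1"] == 1

    def test_zero_participant_counts_zero(self):
        df = pd.DataFrame(
            {
                "participant_id": "P1",
                "date": [day(0)],
                "bud_form_actuations": [0],
                "salbutamol_actuations": [0],
            }
        )
        cl = classify_days(df, make_participants(["P1"]))
        assert count_overuse_days(cl, "HIGH")["P1"] == 0

    def test_unknown_level_raises(self):
        with pytest.raises(ValueError, match="unknown overuse level"):
            count_overuse_days(self._classified(), "MASSIVE")


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    bud=st.integers(0, 60),
    sal=st.integers(0, 60),
    arm=st.sampled_from(["SMART", "STANDARD"]),
)
def test_nesting_invariant_holds_for_any_counts(bud, sal, arm):
    """An extreme day is always also a marked and a high day."""
    df = pd.DataFrame(
        {
            "participant_id": ["P1"],
            "date": [day(0)],
            "bud_form_actuations": [bud],
            "salbutamol_actuations": [sal],
        }
    )
    out = classify_days(df, make_participants(["P1"], arm=arm)).iloc[0]
    assert (not out["extreme"]) or out["marked"]
    assert (not out["marked"]) or out["high"]


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    counts=st.lists(st.integers(0, 50), min_size=5, max_size=20),
    bump=st.integers(1, 10),
)
def test_raising_thresholds_never_increases_counts(counts, bump):
    df = pd.DataFrame(
        {
            "participant_id": "P1",
            "date": [day(i) for i in range(len(counts))],
            "bud_form_actuations": counts,
            "salbutamol_actuations": 0,
        }
    )
    parts = make_participants(["P1"], arm="SMART")
    base = ThresholdConfig()
    raised = ThresholdConfig(
        smart_total_thresholds=tuple(t + bump for t in base.smart_total_thresholds)
    )
    for level in ("HIGH", "MARKED", "EXTREME"):
        n_base = count_overuse_days(classify_days(df, parts, base), level)["P1"]
        n_raised = count_overuse_days(classify_days(df, parts, raised), level)["P1"]
        assert n_raised <= n_base


def test_classification_matches_brute_force_recount_from_events(small_cohort,
                                                                small_classified):
    """Classified flags agree with counting raw events by hand per day."""
    from collections import Counter

    acts = small_cohort.actuations
    arm_of = small_cohort.participants.set_index("participant_id")["arm"]
    counter = Counter(
        zip(acts["participant_id"], acts["timestamp"].dt.normalize(), acts["medication"])
    )
    rng = np.random.default_rng(0)
    sample = small_classified.sample(n=300, random_state=1)
    for _, row in sample.iterrows():
        pid, d = row["participant_id"], row["date"]
        bud = counter.get((pid, d, "BUD_FORM"), 0)
        sal = counter.get((pid, d, "SALBUTAMOL"), 0)
        assert bud == row["bud_form_actuations"]
        assert sal == row["salbutamol_actuations"]
        if arm_of[pid] == "SMART":
            assert row["high"] == (bud > 12)
            assert row["extreme"] == (bud > 20)
        else:
            assert row["high"] == (sal > 16)
            assert row["extreme"] == (sal > 32)
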