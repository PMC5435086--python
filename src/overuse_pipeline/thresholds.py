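"""Classification of calendar days as high / marked / extreme beta-agonist use.

The action plans used in the trial advised medical review once reliever use
exceeded a daily limit; "high", "marked" and "extreme" use are days exceeding
1x, 1.5x and 2x that limit. The thresholds are regimen-specific:

* SMART arm — the single budesonide/formoterol inhaler serves as both
  maintenance and reliever, so overuse is judged on the day's *total*
  budesonide/formoterol actuations: >12, >16 and >20 (i.e. >8, >12 and >16
  in excess of the four scheduled maintenance actuations).
* Standard arm — overuse is judged on salbutamol actuations alone: >16, >24
  and >32. Budesonide/formoterol taken as an unscheduled extra reliever in
  this arm is deliberately not counted, which understates Standard-arm
  overuse but mirrors how the outcome was defined.

All cut-offs are strict (a SMART day of exactly 12 is not high use), and the
flags nest: every extreme day is also a marked and a high day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import SMART

NONE = "NONE"
HIGH = "HIGH"
MARKED = "MARKED"
EXTREME = "EXTREME"
LEVELS = (HIGH, MARKED, EXTREME)

_FLAG_COLS = {HIGH: "high", MARKED: "marked", EXTREME: "extreme"}


@dataclass(frozen=True)
class ThresholdConfig:
    """Strict-greater-than daily actuation cut-offs, per regimen.

    ``smart_mode`` selects between the operational readings of the SMART
    rule: ``"total"`` (default) compares the day's total budesonide/
    formoterol actuations with ``smart_total_thresholds``; ``"excess"``
    subtracts the scheduled maintenance actuations and compares with
    correspondingly reduced cut-offs. With full maintenance adherence the two
    are identical; "total" is kept as the default because it is well defined
    even when maintenance adherence is imperfect.
    """

    smart_total_thresholds: tuple = (12, 16, 20)
    standard_salbutamol_thresholds: tuple = (16, 24, 32)
    maintenance_actuations_per_day: int = 4
    smart_mode: str = "total"

    def __post_init__(self):
        for name in ("smart_total_thresholds", "standard_salbutamol_thresholds"):
            t = getattr(self, name)
            if len(t) != 3 or not (t[0] < t[1] < t[2]):
                raise ValueError(f"{name} must be three strictly increasing cut-offs, got {t}")
        if self.smart_mode not in ("total", "excess"):
            raise ValueError(f"smart_mode must be 'total' or 'excess', got {self.smart_mode!r}")


def classify_days(day_records: pd.DataFrame, participants: pd.DataFrame,
                  config: ThresholdConfig | None = None) -> pd.DataFrame:
    """Attach overuse flags to a frame of per-day actuation totals.

    Adds ``arm``, boolean ``high``/``marked``/``extreme`` columns and the
    categorical ``overuse_level`` (highest level attained, ``NONE`` if the
    day crosses no threshold).
    """
    config = config or ThresholdConfig()
    out = day_records.merge(
        participants[["participant_id", "arm"]], on="participant_id", how="left"
    )
    is_smart = (out["arm"] == SMART).to_numpy()

    if config.smart_mode == "total":
        smart_value = out["bud_form_actuations"].to_numpy()
        smart_cuts = config.smart_total_thresholds
    else:
        smart_value = out["bud_form_actuations"].to_numpy() - config.maintenance_actuations_per_day
        smart_cuts = tuple(t - config.maintenance_actuations_per_day
                           for t in config.smart_total_thresholds)
    std_value = out["salbutamol_actuations"].to_numpy()
    std_cuts = config.standard_salbutamol_thresholds

    for level, s_cut, t_cut in zip(LEVELS, smart_cuts, std_cuts):
        out[_FLAG_COLS[level]] = np.where(is_smart, smart_value > s_cut, std_value > t_cut)

    out["overuse_level"] = np.select(
        [out["extreme"], out["marked"], out["high"]], [EXTREME, MARKED, HIGH], default=NONE
    )
    return out


def classify_day(bud_form_actuations: int, salbutamol_actuations: int, arm: str,
                 config: ThresholdConfig | None = None) -> str:
    """Classify a single day; returns the highest overuse level attained."""
    df = pd.DataFrame(
        {
            "participant_id": ["_"],
            "date": [pd.NaT],
            "bud_form_actuations": [bud_form_actuations],
            "salbutamol_actuations": [salbutamol_actuations],
        }
    )
    parts = pd.DataFrame({"participant_id": ["_"], "arm": [arm]})
    return classify_days(df, parts, config)["overuse_level"].iloc[0]


def _flag_col(level: str) -> str:
    if level not in _FLAG_COLS:
        raise ValueError(f"unknown overuse level {level!r}; expected one of {LEVELS}")
    return _FLAG_COLS[level]


def count_overuse_days(classified_days: pd.DataFrame, level: str) -> pd.Series:
    """Per-participant number of days flagged at ``level`` (0 where none).

    Because the flags nest, counts are monotone: count(EXTREME) <=
    count(MARKED) <= count(HIGH) for every participant.
    """
    col = _flag_col(level)
    counts = classified_days.groupby("participant_id")[col].sum().astype(int)
    all_ids = classified_days["participant_id"].unique()
    return counts.reindex(all_ids, fill_value=0)
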