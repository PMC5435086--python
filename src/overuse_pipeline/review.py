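"""Linking overuse days to medical review under the 48-hour rule.

For every overuse ("index") day the question is whether the participant
attended for medical review either on that day or the next (the 48-hour
window the action plans advise). When a review *is* linked to an index day,
a "stand-down" applies: overuse on the index day, on the review day and in
the 7 days after the review is not counted as overuse-without-review — the
patient has just been seen for this exacerbation. A further review attended
during an open stand-down restarts the 7-day clock, so protection windows
from successive reviews chain.

Operationally, per participant and overuse level:

1. a review date ``r`` is *linked* if some overuse day ``d`` at that level
   satisfies ``r in {d, d+1}``;
2. scanning reviews in date order, a linked review opens a protection window
   ``[r, r+7]``; any review (linked or not) falling inside an open window
   extends it through its own date plus 7 days;
3. an index day linked to a review is itself protected.

An overuse day is counted as "without medical review within 48 h" iff it is
neither reviewed within the window nor inside any stand-down protection.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .thresholds import LEVELS, _flag_col

REVIEW_WINDOW_DAYS = 2   # index day plus the next day
STANDDOWN_DAYS = 7


def _ordinal(d) -> int:
    return pd.Timestamp(d).toordinal()


@dataclass(frozen=True)
class StandDownLedger:
    """The set of calendar dates protected by stand-down for one participant.

    Reconstructible from the participant's review dates plus the overuse
    index days; holds dates as integer day ordinals internally.
    """

    protected_ordinals: frozenset

    @property
    def protected_dates(self) -> set:
        return {date.fromordinal(o) for o in self.protected_ordinals}

    def is_protected(self, d) -> bool:
        return _ordinal(d) in self.protected_ordinals


def reviewed_within_window(index_date, review_dates,
                           window_days: int = REVIEW_WINDOW_DAYS) -> bool:
    """True iff some review falls on the index day or within the next
    ``window_days - 1`` days."""
    idx = _ordinal(index_date)
    revs = {_ordinal(r) for r in review_dates}
    return any(idx + k in revs for k in range(window_days))


def _protected_ordinals(review_ords: set, overuse_ords: set,
                        standdown_days: int = STANDDOWN_DAYS,
                        window_days: int = REVIEW_WINDOW_DAYS) -> set:
    linked_reviews = {
        r for r in review_ords
        if any(r - k in overuse_ords for k in range(window_days))
    }
    protected: set = set()
    active_end = None
    for r in sorted(review_ords):
        inside_open_window = active_end is not None and r <= active_end
        if inside_open_window or r in linked_reviews:
            protected.update(range(r, r + standdown_days + 1))
            active_end = r + standdown_days
    # index days whose linked review happened on the day or the next
    for d in overuse_ords:
        if any(d + k in review_ords for k in range(window_days)):
            protected.add(d)
    return protected


def build_standdown_ledger(review_dates, overuse_dates,
                           standdown_days: int = STANDDOWN_DAYS,
                           window_days: int = REVIEW_WINDOW_DAYS) -> StandDownLedger:
    """Construct the stand-down ledger from review dates and overuse index days."""
    revs = {_ordinal(r) for r in review_dates}
    over = {_ordinal(d) for d in overuse_dates}
    return StandDownLedger(
        frozenset(_protected_ordinals(revs, over, standdown_days, window_days))
    )


def link_reviews(classified_days: pd.DataFrame, reviews: pd.DataFrame,
                 levels=LEVELS,
                 standdown_days: int = STANDDOWN_DAYS,
                 window_days: int = REVIEW_WINDOW_DAYS) -> pd.DataFrame:
    """Evaluate the 48-h rule and stand-down ledger for every overuse day.

    Returns one row per (participant, overuse day, level attained) with
    boolean columns ``reviewed_within_48h``, ``in_standdown`` and
    ``counted_as_unreviewed``. The ledger is built separately per level,
    because index days — and hence linked reviews — are level-specific.
    """
    review_ords_by_pid: dict = {}
    if len(reviews):
        rv = reviews.copy()
        rv["_ord"] = rv["date"].map(_ordinal)
        review_ords_by_pid = {pid: set(g) for pid, g in rv.groupby("participant_id")["_ord"]}

    rows = []
    for pid, g in classified_days.groupby("participant_id", sort=True):
        revs = review_ords_by_pid.get(pid, set())
        ords = g["date"].map(_ordinal).to_numpy()
        for level in levels:
            mask = g[_flag_col(level)].to_numpy()
            if not mask.any():
                continue
            over = set(ords[mask])
            protected = _protected_ordinals(revs, over, standdown_days, window_days)
            for d, dt_ in zip(ords[mask], g["date"].to_numpy()[mask]):
                reviewed = any(d + k in revs for k in range(window_days))
                in_sd = d in protected
                rows.append(
                    (pid, dt_, level, reviewed, in_sd, not reviewed and not in_sd)
                )
    out = pd.DataFrame(
        rows,
        columns=["participant_id", "date", "level", "reviewed_within_48h",
                 "in_standdown", "counted_as_unreviewed"],
    )
    return out


def count_unreviewed_days(outcomes: pd.DataFrame, level: str,
                          participants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-participant unreviewed-day count and proportion at ``level``.

    The denominator is *all* overuse days at the level (stand-down-protected
    days included); the proportion is NaN — excluded from cohort means — for
    participants with no overuse day at the level. Passing ``participants``
    reindexes the result over the full cohort (zero counts, NaN proportion).
    """
    if level not in LEVELS:
        raise ValueError(f"unknown overuse level {level!r}; expected one of {LEVELS}")
    sub = outcomes[outcomes["level"] == level]
    grp = sub.groupby("participant_id")
    res = pd.DataFrame(
        {
            "n_overuse_days": grp.size(),
            "n_unreviewed_days": grp["counted_as_unreviewed"].sum().astype(int),
        }
    )
    if participants is not None:
        res = res.reindex(participants["participant_id"]).fillna(0).astype(int)
    res["proportion_unreviewed"] = np.where(
        res["n_overuse_days"] > 0,
        res["n_unreviewed_days"] / res["n_overuse_days"].replace(0, np.nan),
        np.nan,
    )
    res.index.name = "participant_id"
    return res
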