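"""Severe-exacerbation episodes and peri-exacerbation medication-use windows.

A severe exacerbation is anchored by a systemic-corticosteroid course of at
least 3 days; courses separated by fewer than 7 days (last day of the
earlier course to first day of the later) belong to the same exacerbation,
and the first day of corticosteroid therapy is Day 0. Medication use is
profiled over the 14 days before and after Day 0. For participants with
repeat exacerbations, an episode whose Day 0 falls within 28 days after the
previous retained episode's Day 0 is excluded from the window analysis (it
still counts as an exacerbation event). Dose dumping — at least 100
actuations of one medication within any 3-hour span — is flagged but the
flagged days remain in the profiles.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .events import BUD_FORM, SALBUTAMOL

COURSE_SEPARATION_DAYS = 7
MIN_COURSE_DAYS = 3
OVERLAP_DAYS = 28
WINDOW_DAYS = 14
DOSE_DUMP_COUNT = 100
DOSE_DUMP_HOURS = 3

_DAY = pd.Timedelta(days=1)


def build_episodes(ocs_records: pd.DataFrame,
                   min_course_days: int = MIN_COURSE_DAYS,
                   separation_days: int = COURSE_SEPARATION_DAYS) -> pd.DataFrame:
    """Merge corticosteroid courses into severe-exacerbation episodes.

    Courses of one participant whose start follows the previous course's end
    by fewer than ``separation_days`` days are one episode, anchored at the
    earliest start (Day 0). Merged groups whose total therapy days fall
    short of ``min_course_days`` are not episodes. Overlapping courses merge
    with a warning. The result is order-invariant with respect to the input
    row order and idempotent.

    Returns a frame with one row per episode: ``participant_id``, ``day0``,
    ``course_end`` (last therapy day), ``therapy_days``, ``n_courses``.
    """
    rows = []
    if len(ocs_records) == 0:
        return pd.DataFrame(
            columns=["participant_id", "day0", "course_end", "therapy_days", "n_courses"]
        )
    for pid, g in ocs_records.sort_values(["start_date", "end_date"]).groupby(
        "participant_id", sort=True
    ):
        current = None  # [start, end, therapy-date set, n_courses]
        clusters = []
        for start, end in zip(g["start_date"], g["end_date"]):
            days = set(pd.date_range(start, end, freq="D"))
            if current is None:
                current = [start, end, days, 1]
                continue
            gap = (start - current[1]).days
            if gap <= 0:
                warnings.warn(
                    f"overlapping corticosteroid courses for participant {pid}; merged",
                    stacklevel=2,
                )
            if gap < separation_days:
                current[1] = max(current[1], end)
                current[2] |= days
                current[3] += 1
            else:
                clusters.append(current)
                current = [start, end, days, 1]
        clusters.append(current)
        for start, end, days, n in clusters:
            if len(days) >= min_course_days:
                rows.append((pid, start, end, len(days), n))
    return pd.DataFrame(
        rows, columns=["participant_id", "day0", "course_end", "therapy_days", "n_courses"]
    )


def select_window_episodes(episodes: pd.DataFrame,
                           overlap_days: int = OVERLAP_DAYS,
                           has_monitor_data: pd.Series | None = None) -> pd.DataFrame:
    """Flag which episodes enter the peri-exacerbation window analysis.

    Within each participant (episodes ordered by Day 0), an episode whose
    Day 0 falls within ``overlap_days`` days after the previous retained
    episode's Day 0 is excluded (reason ``overlap_28d``) to avoid the same
    days appearing in two windows. Episodes with no usable monitor data
    (boolean ``has_monitor_data`` indexed like ``episodes``, default all
    True) are excluded with reason ``no_monitor_data`` but still anchor the
    interval rule. Excluded episodes still count as exacerbation events.
    """
    out = episodes.sort_values(["participant_id", "day0"]).copy()
    monitored = (
        has_monitor_data.reindex(out.index).fillna(True).to_numpy(dtype=bool)
        if has_monitor_data is not None
        else np.ones(len(out), dtype=bool)
    )
    included = np.ones(len(out), dtype=bool)
    reason = np.array([""] * len(out), dtype=object)
    for _, idx in out.groupby("participant_id", sort=False).indices.items():
        last_anchor = None
        for i in idx:
            day0 = out["day0"].iloc[i]
            if last_anchor is not None and (day0 - last_anchor).days <= overlap_days:
                included[i] = False
                reason[i] = "overlap_28d"
                continue
            last_anchor = day0
            if not monitored[i]:
                included[i] = False
                reason[i] = "no_monitor_data"
    out["included_in_window_analysis"] = included
    out["exclusion_reason"] = reason
    return out


def extract_window(day0, participant_days: pd.DataFrame,
                   window_days: int = WINDOW_DAYS) -> pd.DataFrame:
    """Per-offset actuation totals around one episode's Day 0.

    Offsets run from ``-window_days`` to ``+window_days``; offset 0 is Day 0.
    Offsets outside the participant's monitoring period are absent (NaN),
    not zero — the zero-filled day records distinguish "no use" from "not
    monitored".
    """
    offsets = np.arange(-window_days, window_days + 1)
    dates = pd.Timestamp(day0) + pd.to_timedelta(offsets, unit="D")
    lookup = participant_days.set_index("date")[
        ["bud_form_actuations", "salbutamol_actuations"]
    ]
    win = lookup.reindex(dates).astype(float)
    win.index = pd.Index(offsets, name="offset")
    return win


def extract_windows(episodes: pd.DataFrame, day_records: pd.DataFrame,
                    window_days: int = WINDOW_DAYS,
                    included_only: bool = True) -> pd.DataFrame:
    """Long-format windows for all (included) episodes.

    Columns: participant_id, day0, offset, bud_form_actuations,
    salbutamol_actuations (NaN where the offset is outside monitoring).
    """
    eps = episodes
    if included_only and "included_in_window_analysis" in eps.columns:
        eps = eps[eps["included_in_window_analysis"]]
    frames = []
    for pid, g in eps.groupby("participant_id", sort=True):
        pdays = day_records[day_records["participant_id"] == pid]
        for day0 in g["day0"]:
            win = extract_window(day0, pdays, window_days).reset_index()
            win.insert(0, "day0", day0)
            win.insert(0, "participant_id", pid)
            frames.append(win)
    if not frames:
        return pd.DataFrame(
            columns=["participant_id", "day0", "offset",
                     "bud_form_actuations", "salbutamol_actuations"]
        )
    return pd.concat(frames, ignore_index=True)


def profile_medians(windows: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Per-offset median and IQR of daily actuations, by arm and medication.

    ``n`` counts episodes contributing data at the offset; offsets with no
    data are absent from the result.
    """
    merged = windows.merge(
        participants[["participant_id", "arm"]], on="participant_id", how="left"
    )
    long = merged.melt(
        id_vars=["participant_id", "day0", "offset", "arm"],
        value_vars=["bud_form_actuations", "salbutamol_actuations"],
        var_name="medication", value_name="actuations",
    )
    long["medication"] = long["medication"].map(
        {"bud_form_actuations": BUD_FORM, "salbutamol_actuations": SALBUTAMOL}
    )
    long = long.dropna(subset=["actuations"])
    out = (
        long.groupby(["arm", "medication", "offset"])["actuations"]
        .agg(
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            n="size",
        )
        .reset_index()
    )
    return out


def detect_dose_dumping(actuation_events: pd.DataFrame,
                        threshold: int = DOSE_DUMP_COUNT,
                        window_hours: float = DOSE_DUMP_HOURS) -> pd.DataFrame:
    """Flag spans where >= ``threshold`` actuations of one medication fall
    within ``window_hours`` hours.

    Every event anchors a candidate window reaching ``window_hours`` forward;
    qualifying windows that overlap coalesce into a single flag carrying the
    span and the largest in-window count. Returns columns participant_id,
    medication, window_start, window_end, actuation_count.
    """
    rows = []
    if len(actuation_events) == 0:
        return pd.DataFrame(
            columns=["participant_id", "medication", "window_start", "window_end",
                     "actuation_count"]
        )
    horizon = pd.Timedelta(hours=window_hours).value
    for (pid, med), g in actuation_events.groupby(["participant_id", "medication"], sort=True):
        t = np.sort(g["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64))
        n = len(t)
        if n < threshold:
            continue
        ends = np.searchsorted(t, t + horizon, side="right") - 1
        counts = ends - np.arange(n) + 1
        qual = np.flatnonzero(counts >= threshold)
        current = None  # [start_i, end_i, max_count]
        flags = []
        for i in qual:
            if current is not None and t[i] <= t[current[1]]:
                current[1] = max(current[1], ends[i])
                current[2] = max(current[2], counts[i])
            else:
                if current is not None:
                    flags.append(current)
                current = [i, ends[i], counts[i]]
        if current is not None:
            flags.append(current)
        for si, ei, c in flags:
            rows.append(
                (pid, med, pd.Timestamp(t[si]), pd.Timestamp(t[ei]), int(c))
            )
    return pd.DataFrame(
        rows, columns=["participant_id", "medication", "window_start", "window_end",
                       "actuation_count"]
    )


def _pct(numerator: int, denominator: int) -> int:
    if denominator == 0:
        return 0
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def preexacerbation_overuse_fraction(episodes: pd.DataFrame,
                                     overuse_outcomes: pd.DataFrame,
                                     level: str,
                                     window_days: int = WINDOW_DAYS) -> dict:
    """Overuse days falling in the 14 days before any included episode.

    The numerator is overuse days at ``level`` (from the review-linkage
    outcomes, which should already be restricted to one arm) landing at
    offsets -14..-1 of an included episode; the denominator is all overuse
    days at the level. Also reports how many of the pre-exacerbation overuse
    days went without medical review within 48 h. Percentages are integer,
    rounded half-up.
    """
    sub = overuse_outcomes[overuse_outcomes["level"] == level]
    eps = episodes
    if len(eps) and "included_in_window_analysis" in eps.columns:
        eps = eps[eps["included_in_window_analysis"].astype(bool)]
    pre: set = set()
    for pid, day0 in zip(eps["participant_id"], eps["day0"]):
        for k in range(1, window_days + 1):
            pre.add((pid, pd.Timestamp(day0) - k * _DAY))
    keys = list(zip(sub["participant_id"], pd.to_datetime(sub["date"])))
    in_pre = np.array([k in pre for k in keys], dtype=bool)
    n_total = len(sub)
    n_pre = int(in_pre.sum())
    n_pre_unreviewed = int(sub.loc[in_pre, "counted_as_unreviewed"].sum())
    return {
        "level": level,
        "n_pre": n_pre,
        "n_total": n_total,
        "pct_pre_of_total": _pct(n_pre, n_total),
        "n_pre_unreviewed": n_pre_unreviewed,
        "pct_pre_unreviewed": _pct(n_pre_unreviewed, n_pre),
    }


def highest_use_summary(windows: pd.DataFrame, medication: str,
                        companion: str | None = None) -> dict:
    """Per-episode maximum daily actuations before and after Day 0.

    For each episode the maximum of ``medication`` over offsets -14..-1
    ("pre") and 0..+14 ("post") is taken; the summary reports the cohort
    median and range of those maxima. When ``companion`` is given (Standard
    arm: salbutamol maxima with companion budesonide/formoterol), the count
    of the companion medication on the day of maximal use is summarised too,
    with the number of episodes taking more than 8 and exactly 0 companion
    actuations on that day. Ties on the maximum resolve to the earliest
    offset.
    """
    med_col = {BUD_FORM: "bud_form_actuations", SALBUTAMOL: "salbutamol_actuations"}[medication]
    comp_col = (
        {BUD_FORM: "bud_form_actuations", SALBUTAMOL: "salbutamol_actuations"}[companion]
        if companion else None
    )
    result: dict = {}
    for name, lo, hi in (("pre", -WINDOW_DAYS, -1), ("post", 0, WINDOW_DAYS)):
        maxima, companions = [], []
        for (_, _), g in windows.groupby(["participant_id", "day0"], sort=True):
            seg = g[(g["offset"] >= lo) & (g["offset"] <= hi)].dropna(subset=[med_col])
            if seg.empty:
                continue
            seg = seg.sort_values("offset")
            imax = seg[med_col].idxmax()   # first occurrence on ties
            maxima.append(seg.loc[imax, med_col])
            if comp_col:
                companions.append(seg.loc[imax, comp_col])
        maxima = np.asarray(maxima, dtype=float)
        block = {
            "n_episodes": len(maxima),
            "median": float(np.median(maxima)) if len(maxima) else np.nan,
            "range": (float(maxima.min()), float(maxima.max())) if len(maxima) else (np.nan, np.nan),
        }
        if comp_col:
            comp = np.asarray(companions, dtype=float)
            block["companion_median"] = float(np.median(comp)) if len(comp) else np.nan
            block["companion_range"] = (
                (float(comp.min()), float(comp.max())) if len(comp) else (np.nan, np.nan)
            )
            block["n_companion_gt8"] = int((comp > 8).sum())
            block["n_companion_zero"] = int((comp == 0).sum())
        result[name] = block
    return result
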