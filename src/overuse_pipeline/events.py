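"""Reading, validation and daily aggregation of inhaler-monitor event tables.

Four delimited-text tables describe a monitored cohort:

* ``participants`` — one row per participant with treatment arm and the
  monitoring period (``monitor_start`` .. ``monitor_end``, inclusive).
* ``actuations`` — one row per inhaler actuation, time-stamped to the second
  by the electronic monitor.
* ``reviews`` — one row per medical-review attendance (primary care,
  after-hours clinic or hospital), dated to the calendar day.
* ``ocs`` — systemic (oral) corticosteroid course records with start and end
  dates.

:func:`load_events` validates the bundle; :func:`aggregate_days` resolves the
actuation stream into one record per participant per calendar day of
monitoring, zero-filled so that downstream proportions have an exposure-day
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SMART = "SMART"
STANDARD = "STANDARD"
ARMS = (SMART, STANDARD)

BUD_FORM = "BUD_FORM"
SALBUTAMOL = "SALBUTAMOL"
MEDICATIONS = (BUD_FORM, SALBUTAMOL)

REVIEW_SETTINGS = ("PRIMARY_CARE", "AFTER_HOURS", "HOSPITAL")


class ValidationError(ValueError):
    """Raised when an input table violates a cohort invariant.

    ``report`` holds the offending rows (with a ``reason`` column) so the
    caller can see exactly which records broke which rule.
    """

    def __init__(self, message: str, report: pd.DataFrame | None = None):
        super().__init__(message)
        self.report = report


class ParseError(ValidationError):
    """Raised for malformed timestamps/dates; the report carries line numbers."""


@dataclass
class Cohort:
    """A validated bundle of the four input tables.

    ``rejected`` maps table name -> frame of rows dropped with a reason
    (currently only out-of-monitoring-period events are dropped rather than
    raising).
    """

    participants: pd.DataFrame
    actuations: pd.DataFrame
    reviews: pd.DataFrame
    ocs_courses: pd.DataFrame
    rejected: dict = field(default_factory=dict)

    @property
    def participant_ids(self) -> list:
        return list(self.participants["participant_id"])


def _as_frame(table, name: str) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table.reset_index(drop=True).copy()
    try:
        return pd.read_csv(table, dtype=str)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValidationError(f"could not parse {name} table: {exc}") from exc


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{name} table is missing columns {missing}")


def _parse_datetime(series: pd.Series, name: str, tz: str | None = None) -> pd.Series:
    parsed = pd.to_datetime(series, errors="coerce", format="ISO8601")
    bad = parsed.isna() & series.notna()
    if bad.any():
        report = pd.DataFrame(
            {"line": series.index[bad] + 2, "value": series[bad], "reason": "unparseable"}
        )
        raise ParseError(
            f"malformed {name} at line(s) {list(report['line'])}", report
        )
    if tz is not None:
        if parsed.dt.tz is None:
            parsed = parsed.dt.tz_localize(tz, ambiguous="NaT", nonexistent="NaT")
        parsed = parsed.dt.tz_convert(tz).dt.tz_localize(None)
    elif parsed.dt.tz is not None:
        parsed = parsed.dt.tz_localize(None)
    return parsed


def _check_enum(df: pd.DataFrame, col: str, allowed, name: str) -> None:
    bad = ~df[col].isin(allowed)
    if bad.any():
        report = df.loc[bad].assign(reason=f"{col} not in {allowed}")
        raise ValidationError(
            f"{name} table has invalid {col} value(s): {sorted(df.loc[bad, col].unique())}",
            report,
        )


def _check_known_ids(df: pd.DataFrame, known: set, name: str) -> None:
    bad = ~df["participant_id"].isin(known)
    if bad.any():
        report = df.loc[bad].assign(reason="unknown participant_id")
        raise ValidationError(
            f"{name} table references unknown participant id(s): "
            f"{sorted(df.loc[bad, 'participant_id'].unique())}",
            report,
        )


def load_events(actuation_table, review_table, ocs_table, participant_table,
                tz: str | None = None) -> Cohort:
    """Read and validate the four event tables into a :class:`Cohort`.

    Parameters may be file paths or already-loaded data frames. Timestamps are
    ISO-8601; ``tz`` optionally names the study-local timezone used to resolve
    calendar days (timestamps are converted then made naive).

    Raises :class:`ValidationError` for unknown participant ids, invalid enum
    values, a salbutamol actuation recorded for a SMART-arm participant, or
    inverted date ranges; raises :class:`ParseError` for malformed
    timestamps. Rows whose timestamp/date falls outside the participant's
    monitoring period are *rejected* (dropped) and reported in
    ``cohort.rejected`` rather than raising.
    """
    participants = _as_frame(participant_table, "participants")
    _require_columns(
        participants, ["participant_id", "arm", "monitor_start", "monitor_end"],
        "participants",
    )
    if participants["participant_id"].duplicated().any():
        dup = participants[participants["participant_id"].duplicated(keep=False)]
        raise ValidationError("duplicate participant ids", dup.assign(reason="duplicate id"))
    _check_enum(participants, "arm", ARMS, "participants")
    participants["monitor_start"] = _parse_datetime(participants["monitor_start"], "monitor_start")
    participants["monitor_end"] = _parse_datetime(participants["monitor_end"], "monitor_end")
    bad_span = participants["monitor_end"] < participants["monitor_start"]
    if bad_span.any():
        raise ValidationError(
            "monitor_end precedes monitor_start",
            participants[bad_span].assign(reason="monitor_end < monitor_start"),
        )
    known = set(participants["participant_id"])
    span = participants.set_index("participant_id")[["monitor_start", "monitor_end", "arm"]]

    actuations = _as_frame(actuation_table, "actuations")
    _require_columns(actuations, ["participant_id", "medication", "timestamp"], "actuations")
    _check_known_ids(actuations, known, "actuations")
    _check_enum(actuations, "medication", MEDICATIONS, "actuations")
    actuations["timestamp"] = _parse_datetime(actuations["timestamp"], "timestamp", tz=tz)

    # Regimen invariant: SMART participants carry no salbutamol inhaler.
    arm_of = span["arm"]
    act_arm = actuations["participant_id"].map(arm_of)
    salb_in_smart = (actuations["medication"] == SALBUTAMOL) & (act_arm == SMART)
    if salb_in_smart.any():
        raise ValidationError(
            "rule violated: SALBUTAMOL actuations recorded for SMART-arm "
            f"participant(s) {sorted(actuations.loc[salb_in_smart, 'participant_id'].unique())}",
            actuations[salb_in_smart].assign(reason="SALBUTAMOL event for SMART participant"),
        )

    rejected: dict[str, pd.DataFrame] = {}

    start = actuations["participant_id"].map(span["monitor_start"])
    end = actuations["participant_id"].map(span["monitor_end"]) + pd.Timedelta(days=1)
    out = (actuations["timestamp"] < start) | (actuations["timestamp"] >= end)
    if out.any():
        rejected["actuations"] = actuations[out].assign(reason="timestamp outside monitoring period")
    actuations = actuations[~out].reset_index(drop=True)

    reviews = _as_frame(review_table, "reviews")
    _require_columns(reviews, ["participant_id", "date", "setting"], "reviews")
    if len(reviews):
        _check_known_ids(reviews, known, "reviews")
        _check_enum(reviews, "setting", REVIEW_SETTINGS, "reviews")
        reviews["date"] = _parse_datetime(reviews["date"], "date")
        rstart = reviews["participant_id"].map(span["monitor_start"])
        rend = reviews["participant_id"].map(span["monitor_end"])
        out = (reviews["date"] < rstart) | (reviews["date"] > rend)
        if out.any():
            rejected["reviews"] = reviews[out].assign(reason="date outside monitoring period")
        reviews = reviews[~out].reset_index(drop=True)
    else:
        reviews = reviews.assign(date=pd.to_datetime(reviews.get("date", pd.Series(dtype=str))))

    ocs = _as_frame(ocs_table, "ocs")
    _require_columns(ocs, ["participant_id", "start_date", "end_date"], "ocs")
    if len(ocs):
        _check_known_ids(ocs, known, "ocs")
        ocs["start_date"] = _parse_datetime(ocs["start_date"], "start_date")
        ocs["end_date"] = _parse_datetime(ocs["end_date"], "end_date")
        bad = ocs["end_date"] < ocs["start_date"]
        if bad.any():
            raise ValidationError(
                "OCS course end_date precedes start_date",
                ocs[bad].assign(reason="end_date < start_date"),
            )
    else:
        ocs = ocs.assign(
            start_date=pd.to_datetime(ocs.get("start_date", pd.Series(dtype=str))),
            end_date=pd.to_datetime(ocs.get("end_date", pd.Series(dtype=str))),
        )

    return Cohort(
        participants=participants,
        actuations=actuations,
        reviews=reviews,
        ocs_courses=ocs,
        rejected=rejected,
    )


def aggregate_days(cohort: Cohort) -> pd.DataFrame:
    """Resolve the actuation stream into per-participant per-day totals.

    Returns one row per participant per calendar day of the monitoring period
    with integer columns ``bud_form_actuations`` and ``salbutamol_actuations``.
    Days with no recorded actuations are explicit zero rows, so the frame's
    row count equals total exposure days. The calendar day of an event is the
    date component of its timestamp (midnight-to-midnight in study-local
    time).
    """
    parts = cohort.participants
    n_days = (parts["monitor_end"] - parts["monitor_start"]).dt.days.to_numpy() + 1
    pid_rep = np.repeat(parts["participant_id"].to_numpy(), n_days)
    offsets = np.concatenate([np.arange(n) for n in n_days]) if len(parts) else np.array([], dtype=int)
    start_rep = np.repeat(parts["monitor_start"].to_numpy(), n_days)
    dates = start_rep + offsets.astype("timedelta64[D]")
    grid = pd.DataFrame({"participant_id": pid_rep, "date": dates})

    if len(cohort.actuations):
        counts = (
            cohort.actuations
            .assign(date=cohort.actuations["timestamp"].dt.normalize())
            .groupby(["participant_id", "date", "medication"])
            .size()
            .unstack("medication", fill_value=0)
            .reset_index()
        )
    else:
        counts = pd.DataFrame(columns=["participant_id", "date"])
    for med in MEDICATIONS:
        if med not in counts.columns:
            counts[med] = 0

    out = grid.merge(counts, on=["participant_id", "date"], how="left")
    out[BUD_FORM] = out[BUD_FORM].fillna(0).astype(int)
    out[SALBUTAMOL] = out[SALBUTAMOL].fillna(0).astype(int)
    return out.rename(
        columns={BUD_FORM: "bud_form_actuations", SALBUTAMOL: "salbutamol_actuations"}
    )
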