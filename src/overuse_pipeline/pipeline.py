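"""End-to-end orchestration: load -> classify -> link -> episodes -> stats.

:func:`run_pipeline` runs every stage on the four input tables and writes
the report bundle: one overuse summary table per level (rows mirroring the
trial's outcome tables for each arm), the between-arm comparisons, the
per-overuse-day review-linkage table, the exacerbation episode list,
peri-exacerbation window profiles and dose-dumping flags, plus a run log
with the configuration echo and per-stage row counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import ARMS, BUD_FORM, SALBUTAMOL, SMART, STANDARD, Cohort, aggregate_days, load_events
from .thresholds import LEVELS, ThresholdConfig, classify_days, count_overuse_days
from .review import REVIEW_WINDOW_DAYS, STANDDOWN_DAYS, count_unreviewed_days, link_reviews
from . import episodes as ep
from .stats import TwoByTwo, proportion_summary, rate_ratio, relative_risk

logger = logging.getLogger("overuse_pipeline")


@dataclass
class RunConfig:
    """Paths, thresholds and window parameters for a pipeline run.

    All window parameters default to the analysis constants: a 48-h review
    window (index day plus the next), 7-day restartable stand-down, 7-day
    corticosteroid course separation, 28-day window-overlap exclusion and
    the 100-actuations-in-3-h dose-dumping rule.
    """

    actuations: str = "actuations.csv"
    reviews: str = "reviews.csv"
    ocs: str = "ocs.csv"
    participants: str = "participants.csv"
    outdir: str = "results"
    tz: str | None = None
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    review_window_days: int = REVIEW_WINDOW_DAYS
    standdown_days: int = STANDDOWN_DAYS
    course_separation_days: int = ep.COURSE_SEPARATION_DAYS
    min_course_days: int = ep.MIN_COURSE_DAYS
    overlap_days: int = ep.OVERLAP_DAYS
    dose_dump_count: int = ep.DOSE_DUMP_COUNT
    dose_dump_hours: float = ep.DOSE_DUMP_HOURS
    log_level: str = "INFO"

    def __post_init__(self):
        for name in ("review_window_days", "standdown_days", "course_separation_days",
                     "min_course_days", "overlap_days", "dose_dump_count"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.dose_dump_hours <= 0:
            raise ValueError("dose_dump_hours must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr is not None:
            cfg.thresholds = ThresholdConfig(
                smart_total_thresholds=tuple(thr.get("smart_total_thresholds", (12, 16, 20))),
                standard_salbutamol_thresholds=tuple(
                    thr.get("standard_salbutamol_thresholds", (16, 24, 32))
                ),
                maintenance_actuations_per_day=thr.get("maintenance_actuations_per_day", 4),
                smart_mode=thr.get("smart_mode", "total"),
            )
        return cfg


def _arm_level_summary(level: str, arm: str, parts: pd.DataFrame,
                       classified: pd.DataFrame, outcomes: pd.DataFrame) -> dict:
    ids = parts.loc[parts["arm"] == arm, "participant_id"]
    n = len(ids)
    arm_class = classified[classified["participant_id"].isin(set(ids))]
    days = count_overuse_days(arm_class, level).reindex(ids, fill_value=0)
    linking = count_unreviewed_days(
        outcomes[outcomes["participant_id"].isin(set(ids))], level,
        participants=parts[parts["arm"] == arm],
    )
    with_ep = days[days > 0]
    unrev = linking.loc[with_ep.index, "n_unreviewed_days"]
    props = linking["proportion_unreviewed"]
    ps = proportion_summary(props)

    def block(s: pd.Series) -> dict:
        if len(s) == 0:
            return {"mean": np.nan, "sd": np.nan, "median": np.nan,
                    "q1": np.nan, "q3": np.nan, "min": np.nan, "max": np.nan}
        return {
            "mean": float(s.mean()),
            "sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0,
            "median": float(s.median()),
            "q1": float(s.quantile(0.25)),
            "q3": float(s.quantile(0.75)),
            "min": float(s.min()),
            "max": float(s.max()),
        }

    return {
        "level": level,
        "arm": arm,
        "n": n,
        "n_with_episode": int((days > 0).sum()),
        "pct_with_episode": float(100.0 * (days > 0).mean()) if n else np.nan,
        "days": block(days),
        "days_with_episode": block(with_ep),
        "unreviewed_days_with_episode": block(unrev),
        "proportion_unreviewed": ps,
    }


def _summary_rows(summaries: list) -> pd.DataFrame:
    rows = []
    for s in summaries:
        flat = {"level": s["level"], "arm": s["arm"], "n": s["n"],
                "n_with_episode": s["n_with_episode"],
                "pct_with_episode": s["pct_with_episode"]}
        for key in ("days", "days_with_episode", "unreviewed_days_with_episode",
                    "proportion_unreviewed"):
            for stat, val in s[key].items():
                flat[f"{key}_{stat}"] = val
        rows.append(flat)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``.

    ``cohort`` may be passed to skip file loading (e.g. freshly generated
    tables). Returns a dict of the in-memory result frames.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    try:
        return _run(config, cohort, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, cohort: Cohort | None, outdir: Path) -> dict:
    logger.info("config: %s", asdict(config))
    if cohort is None:
        cohort = load_events(config.actuations, config.reviews, config.ocs,
                             config.participants, tz=config.tz)
    parts = cohort.participants
    logger.info(
        "stage load: %d participants, %d actuations (%d rejected), %d reviews, %d OCS courses",
        len(parts), len(cohort.actuations),
        sum(len(v) for v in cohort.rejected.values()), len(cohort.reviews),
        len(cohort.ocs_courses),
    )

    days = aggregate_days(cohort)
    expected_days = int(((parts["monitor_end"] - parts["monitor_start"]).dt.days + 1).sum())
    assert len(days) == expected_days, "day-grid row count must equal total exposure days"
    assert int(days[["bud_form_actuations", "salbutamol_actuations"]].to_numpy().sum()) \
        == len(cohort.actuations), "daily totals must conserve the validated event count"
    logger.info("stage aggregate: %d participant-days", len(days))

    classified = classify_days(days, parts, config.thresholds)
    outcomes = link_reviews(classified, cohort.reviews,
                            standdown_days=config.standdown_days,
                            window_days=config.review_window_days)
    logger.info("stage link: %d overuse day-level rows", len(outcomes))

    summaries, comparisons = [], []
    for level in LEVELS:
        by_arm = {
            arm: _arm_level_summary(level, arm, parts, classified, outcomes)
            for arm in ARMS
        }
        summaries.extend(by_arm.values())

        rr = relative_risk(TwoByTwo(
            by_arm[SMART]["n_with_episode"], by_arm[SMART]["n"],
            by_arm[STANDARD]["n_with_episode"], by_arm[STANDARD]["n"],
        ))
        comparisons.append({"outcome": "at_least_one_episode", "level": level, **asdict(rr)})

        exposure, counts, unrev_counts = {}, {}, {}
        for arm in ARMS:
            ids = parts.loc[parts["arm"] == arm, "participant_id"]
            arm_class = classified[classified["participant_id"].isin(set(ids))]
            counts[arm] = count_overuse_days(arm_class, level).reindex(ids, fill_value=0).to_numpy()
            linking = count_unreviewed_days(
                outcomes[outcomes["participant_id"].isin(set(ids))], level,
                participants=parts[parts["arm"] == arm])
            unrev_counts[arm] = linking["n_unreviewed_days"].to_numpy()
            exposure[arm] = (
                (parts.loc[parts["arm"] == arm, "monitor_end"]
                 - parts.loc[parts["arm"] == arm, "monitor_start"]).dt.days + 1
            ).to_numpy()
        for outcome, cts in (("days", counts), ("unreviewed_days", unrev_counts)):
            comp = rate_ratio(cts[SMART], exposure[SMART], cts[STANDARD], exposure[STANDARD])
            comparisons.append({"outcome": outcome, "level": level, **asdict(comp)})

    episodes = ep.build_episodes(cohort.ocs_courses,
                                 min_course_days=config.min_course_days,
                                 separation_days=config.course_separation_days)
    episodes = ep.select_window_episodes(episodes, overlap_days=config.overlap_days)
    logger.info("stage episodes: %d episodes, %d included in window analysis",
                len(episodes), int(episodes["included_in_window_analysis"].sum()))

    ex_counts, ex_exposure = {}, {}
    for arm in ARMS:
        ids = parts.loc[parts["arm"] == arm, "participant_id"]
        ex_counts[arm] = (
            episodes.groupby("participant_id").size().reindex(ids).fillna(0).to_numpy()
        )
        ex_exposure[arm] = (
            (parts.loc[parts["arm"] == arm, "monitor_end"]
             - parts.loc[parts["arm"] == arm, "monitor_start"]).dt.days + 1
        ).to_numpy()
    if len(episodes):
        comp = rate_ratio(ex_counts[SMART], ex_exposure[SMART],
                          ex_counts[STANDARD], ex_exposure[STANDARD])
        comparisons.append({"outcome": "exacerbations", "level": "", **asdict(comp)})

    windows = ep.extract_windows(episodes, days)
    profiles = ep.profile_medians(windows, parts) if len(windows) else pd.DataFrame(
        columns=["arm", "medication", "offset", "median", "q1", "q3", "n"])
    dumping = ep.detect_dose_dumping(cohort.actuations,
                                     threshold=config.dose_dump_count,
                                     window_hours=config.dose_dump_hours)
    logger.info("stage windows: %d window rows, %d dose-dump flags",
                len(windows), len(dumping))

    table2 = _summary_rows(summaries)
    comparisons_df = pd.DataFrame(comparisons)

    results = {
        "table2_high": table2[table2["level"] == "HIGH"],
        "table2_marked": table2[table2["level"] == "MARKED"],
        "table2_extreme": table2[table2["level"] == "EXTREME"],
        "comparisons": comparisons_df,
        "overuse_review": outcomes,
        "episodes": episodes,
        "window_profiles": profiles,
        "dose_dump_flags": dumping,
        "day_records": classified,
    }
    for name in ("table2_high", "table2_marked", "table2_extreme", "comparisons",
                 "overuse_review", "episodes", "window_profiles", "dose_dump_flags"):
        results[name].to_csv(outdir / f"{name}.csv", index=False)
        logger.info("wrote %s.csv (%d rows)", name, len(results[name]))
    return results
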