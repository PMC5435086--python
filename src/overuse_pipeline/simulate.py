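"""Synthetic two-arm monitored-inhaler cohorts.

The generator emulates the statistical structure of a 24-week, 303-participant
randomised trial of SMART (single budesonide/formoterol inhaler for
maintenance and relief) versus Standard (fixed-dose budesonide/formoterol
plus salbutamol reliever), with every actuation time-stamped by an
electronic monitor. It produces the four delimited tables the pipeline
ingests (participants, actuations, reviews, corticosteroid courses) so
every analysis stage runs at desk scale with no external data.

Per day and participant:

* maintenance budesonide/formoterol actuations are Binomial(4, adherence);
* baseline reliever actuations (budesonide/formoterol extra doses in SMART,
  salbutamol in Standard) are negative-binomial with mean
  ``baseline_reliever_rate``;
* overuse arrives in multi-day blocks (negative-binomial number of blocks
  per participant, geometric block duration, mean 3 days); each block day is
  assigned a magnitude (high / marked / extreme) and its reliever count is
  drawn from that magnitude's band, so day counts cluster the way the
  trial's day-count distributions do;
* severe exacerbations arrive per participant at the arm's configured rate;
  each anchors a 3-7-day corticosteroid course and an arm-specific
  medication-use ramp (SMART: rising use from 5 days before Day 0;
  Standard: variable use from day -14 spiking the day before, both decaying
  to baseline by about day +10);
* each overuse episode (maximal run of consecutive overuse days) prompts a
  medical review with probability ``review_probability_per_overuse_episode``
  at a lag of 0-1 days from its first day; reviews also
  occur at Day 0 of most exacerbations and sporadically at random.

Generation is fully reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .events import ARMS, BUD_FORM, SALBUTAMOL, SMART, STANDARD, load_events, aggregate_days
from .thresholds import EXTREME, HIGH, LEVELS, MARKED, ThresholdConfig, classify_days
from .review import count_unreviewed_days, link_reviews
from .episodes import build_episodes
from .stats import rate_ratio

# Additive mean actuations around Day 0 of an exacerbation, by offset.
# Calibrated so the median peri-exacerbation day totals peak around 11-13
# actuations (maintenance plus baseline reliever included): typical
# exacerbation days sit at or just below the overuse thresholds, and only
# the upper tail of episodes crosses them.
SMART_RAMP = {-5: 1, -4: 2, -3: 3, -2: 4, -1: 5, 0: 6, 1: 6, 2: 6, 3: 5,
              4: 5, 5: 4, 6: 3, 7: 2, 8: 1, 9: 1}
STANDARD_RAMP = {**{k: 1 for k in range(-14, -1)},
                 -1: 9, 0: 11, 1: 8, 2: 6, 3: 4, 4: 3, 5: 2, 6: 1, 7: 1, 8: 1, 9: 1}

# Reliever-count bands (inclusive) drawn for overuse-block days, chosen so a
# block day lands exactly at its assigned magnitude under the default
# thresholds. SMART bands are on the day's *total* budesonide/formoterol.
SMART_BANDS = {HIGH: (13, 16), MARKED: (17, 20), EXTREME: (21, 40)}
STANDARD_BANDS = {HIGH: (17, 24), MARKED: (25, 32), EXTREME: (33, 60)}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the trial's design (arm sizes, 168 monitored days,
    baseline reliever use of about 2 actuations/day, exacerbation rates of
    35/151 and 66/152 events per participant) and a review-seeking
    probability of 0.06 per overuse episode.
    """

    n_smart: int = 151
    n_standard: int = 152
    n_days: int = 168
    start_date: date = date(2013, 3, 1)
    baseline_reliever_rate: float = 2.0
    reliever_dispersion: float = 10.0         # NB shape k; variance = m + m^2/k
    maintenance_actuations_per_day: int = 4
    maintenance_adherence: float = 0.8
    # Overuse blocks per participant per period: negative-binomial, with
    # means/shapes calibrated so about half of each arm has at least one
    # high-use day while the Standard arm accrues more total overuse days
    # concentrated in fewer, longer-tailed participants.
    overuse_episode_mean: dict = field(
        default_factory=lambda: {SMART: 1.5, STANDARD: 2.7}
    )
    overuse_episode_shape: dict = field(
        default_factory=lambda: {SMART: 0.5, STANDARD: 0.25}
    )
    overuse_episode_duration_mean: float = 3.0
    overuse_magnitude: dict = field(
        default_factory=lambda: {HIGH: 0.5, MARKED: 0.2, EXTREME: 0.3}
    )
    review_probability_per_overuse_episode: float = 0.06
    background_review_rate: float = 0.4       # expected attendances / participant / period
    exacerbation_rate: dict = field(
        default_factory=lambda: {SMART: 35 / 151, STANDARD: 66 / 152}
    )
    # Probability that Day 0 of a corticosteroid course coincides with a
    # recorded medical review; kept modest because action plans allowed
    # self-started prednisone courses without an attendance.
    review_at_exacerbation_probability: float = 0.25
    ocs_course_days: tuple = (3, 7)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)

    def __post_init__(self):
        probs = {
            "maintenance_adherence": self.maintenance_adherence,
            "review_probability_per_overuse_episode": self.review_probability_per_overuse_episode,
            "review_at_exacerbation_probability": self.review_at_exacerbation_probability,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("baseline_reliever_rate", "background_review_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if abs(sum(self.overuse_magnitude.get(l, 0.0) for l in LEVELS) - 1.0) > 1e-9:
            raise ValueError("overuse_magnitude must sum to 1 over HIGH/MARKED/EXTREME")
        if self.n_days < 40:
            raise ValueError(
                "n_days must be at least 40 so exacerbation ramps and "
                "peri-exacerbation windows fit inside the monitoring period"
            )

    @property
    def configured_exacerbation_rate_ratio(self) -> float:
        return self.exacerbation_rate[SMART] / self.exacerbation_rate[STANDARD]


def _nb(rng, mean, shape, size):
    if mean <= 0:
        return np.zeros(size, dtype=int)
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p, size)


def _draw_day0s(rng, n_events: int, n_days: int, min_sep: int = 14) -> list:
    """Exacerbation anchor days for one participant: uniform in the interior
    of the monitoring period, pairwise separated by at least ``min_sep`` days.

    With courses of at most 7 days, a 14-day separation keeps every drawn
    exacerbation a distinct episode under the 7-day course-separation rule
    (so generated counts are the ground truth for recovery experiments),
    while still allowing repeat episodes within 28 days that the window
    analysis must exclude."""
    lo, hi = 15, n_days - 16
    chosen: list = []
    attempts = 0
    while len(chosen) < n_events and attempts < 200:
        c = int(rng.integers(lo, hi + 1))
        if all(abs(c - o) >= min_sep for o in chosen):
            chosen.append(c)
        attempts += 1
    return sorted(chosen)


def generate_cohort(config: SyntheticCohortConfig | None = None, seed: int = 0,
                    return_truth: bool = False):
    """Generate the four input tables (and optionally ground-truth arrays).

    Returns a dict with keys ``participants``, ``actuations``, ``reviews``,
    ``ocs`` (data frames ready for :func:`overuse_pipeline.events.load_events`).
    With ``return_truth=True`` a second dict carries the generator's internal
    day-count matrices and review-day sets, keyed by arm, for end-to-end
    recovery checks.
    """
    config = config or SyntheticCohortConfig()
    rng = np.random.default_rng(seed)
    d = config.n_days
    start = pd.Timestamp(config.start_date)
    thr = config.thresholds

    part_rows, act_frames, review_rows, ocs_rows = [], [], [], []
    truth: dict = {}

    for arm, n, prefix in ((SMART, config.n_smart, "SM"), (STANDARD, config.n_standard, "ST")):
        ids = np.array([f"{prefix}{i + 1:03d}" for i in range(n)])
        maint = rng.binomial(config.maintenance_actuations_per_day,
                             config.maintenance_adherence, (n, d))
        reliever = _nb(rng, config.baseline_reliever_rate, config.reliever_dispersion, (n, d))
        bud = maint + (reliever if arm == SMART else 0)
        sal = reliever.copy() if arm == STANDARD else np.zeros((n, d), dtype=int)

        # overuse blocks
        n_blocks = _nb(rng, config.overuse_episode_mean[arm],
                       config.overuse_episode_shape[arm], n)
        bands = SMART_BANDS if arm == SMART else STANDARD_BANDS
        mag_levels = list(LEVELS)
        mag_p = np.array([config.overuse_magnitude[l] for l in mag_levels])
        for i in range(n):
            for _ in range(n_blocks[i]):
                bstart = int(rng.integers(0, d))
                dur = int(rng.geometric(1.0 / config.overuse_episode_duration_mean))
                for day in range(bstart, min(bstart + dur, d)):
                    level = mag_levels[rng.choice(3, p=mag_p)]
                    lo, hi = bands[level]
                    target = int(rng.integers(lo, hi + 1))
                    if arm == SMART:
                        bud[i, day] = target
                    else:
                        sal[i, day] = target

        # severe exacerbations: corticosteroid course + use ramp
        n_ex = rng.poisson(config.exacerbation_rate[arm], n)
        ramp = SMART_RAMP if arm == SMART else STANDARD_RAMP
        for i in range(n):
            for day0 in _draw_day0s(rng, n_ex[i], d):
                length = int(rng.integers(config.ocs_course_days[0],
                                          config.ocs_course_days[1] + 1))
                ocs_rows.append(
                    (ids[i], start + pd.Timedelta(days=day0),
                     start + pd.Timedelta(days=day0 + length - 1))
                )
                for off, mean in ramp.items():
                    day = day0 + off
                    if 0 <= day < d:
                        extra = rng.poisson(mean)
                        if arm == SMART:
                            bud[i, day] += extra
                        else:
                            sal[i, day] += extra
                if rng.random() < config.review_at_exacerbation_probability:
                    setting = "HOSPITAL" if rng.random() < 0.3 else "PRIMARY_CARE"
                    review_rows.append((ids[i], start + pd.Timedelta(days=day0), setting))

        # review-seeking after overuse (HIGH threshold at either arm).
        # Care-seeking is decided once per overuse episode — a maximal run of
        # consecutive overuse days — on its first day, with a fresh decision
        # whenever overuse persists beyond the stand-down coverage of an
        # earlier review. This makes the probability that an overuse episode
        # prompts review equal to the configured value, so the cohort mean
        # proportion of overuse days without review within 48 h sits just
        # below one minus that probability.
        if arm == SMART:
            over_mask = bud > thr.smart_total_thresholds[0]
        else:
            over_mask = sal > thr.standard_salbutamol_thresholds[0]
        p_review = config.review_probability_per_overuse_episode
        for i in range(n):
            over_days = np.flatnonzero(over_mask[i])
            covered_until = -1
            declined_run_end = -2
            prev_day = -2
            for day in over_days:
                new_run = day > prev_day + 1
                prev_day = day
                if day <= covered_until:
                    continue
                if not new_run and day <= declined_run_end:
                    continue
                if rng.random() < p_review:
                    rday = min(int(day) + int(rng.integers(0, 2)), d - 1)
                    setting = "AFTER_HOURS" if rng.random() < 0.2 else "PRIMARY_CARE"
                    review_rows.append(
                        (ids[i], start + pd.Timedelta(days=rday), setting)
                    )
                    covered_until = rday + 7
                else:
                    # declined for the rest of this run
                    run_end = day
                    while run_end + 1 < d and over_mask[i, run_end + 1]:
                        run_end += 1
                    declined_run_end = run_end

        # sporadic background attendances
        n_bg = rng.poisson(config.background_review_rate, n)
        for i in range(n):
            for day in rng.integers(0, d, size=n_bg[i]):
                review_rows.append((ids[i], start + pd.Timedelta(days=int(day)), "PRIMARY_CARE"))

        # expand day counts into second-resolution actuation events
        day_dates = start + pd.to_timedelta(np.arange(d), unit="D")
        for med, mat in ((BUD_FORM, bud), (SALBUTAMOL, sal)):
            counts = mat.ravel()
            if counts.sum() == 0:
                continue
            pid_rep = np.repeat(np.repeat(ids, d), counts)
            date_rep = np.repeat(np.tile(day_dates.to_numpy(), n), counts)
            secs = rng.integers(0, 86400, size=counts.sum())
            ts = date_rep + secs.astype("timedelta64[s]")
            act_frames.append(
                pd.DataFrame({"participant_id": pid_rep, "medication": med, "timestamp": ts})
            )

        for pid in ids:
            part_rows.append((pid, arm, start, start + pd.Timedelta(days=d - 1)))
        if return_truth:
            truth[arm] = {
                "ids": ids, "bud": bud, "sal": sal, "over_mask": over_mask,
                "n_exacerbations": n_ex,
            }

    participants = pd.DataFrame(
        part_rows, columns=["participant_id", "arm", "monitor_start", "monitor_end"]
    )
    actuations = (
        pd.concat(act_frames, ignore_index=True)
        .sort_values(["participant_id", "timestamp", "medication"], kind="mergesort")
        .reset_index(drop=True)
        if act_frames
        else pd.DataFrame(columns=["participant_id", "medication", "timestamp"])
    )
    reviews = (
        pd.DataFrame(review_rows, columns=["participant_id", "date", "setting"])
        .drop_duplicates()
        .sort_values(["participant_id", "date", "setting"], kind="mergesort")
        .reset_index(drop=True)
    )
    ocs = (
        pd.DataFrame(ocs_rows, columns=["participant_id", "start_date", "end_date"])
        .sort_values(["participant_id", "start_date"], kind="mergesort")
        .reset_index(drop=True)
    )
    tables = {"participants": participants, "actuations": actuations,
              "reviews": reviews, "ocs": ocs}
    return (tables, truth) if return_truth else tables


def write_cohort(tables: dict, outdir) -> dict:
    """Write the four tables as CSV (ISO dates, second-resolution timestamps)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    formats = {
        "participants": {"monitor_start": "%Y-%m-%d", "monitor_end": "%Y-%m-%d"},
        "actuations": {"timestamp": "%Y-%m-%d %H:%M:%S"},
        "reviews": {"date": "%Y-%m-%d"},
        "ocs": {"start_date": "%Y-%m-%d", "end_date": "%Y-%m-%d"},
    }
    for name, df in tables.items():
        df = df.copy()
        for col, fmt in formats.get(name, {}).items():
            df[col] = pd.to_datetime(df[col]).dt.strftime(fmt)
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def recovery_experiment(config: SyntheticCohortConfig | None = None,
                        n_replicates: int = 20, seed: int = 0,
                        level: str = HIGH) -> tuple[pd.DataFrame, dict]:
    """Repeatedly generate a cohort, run the full pipeline, and compare the
    recovered quantities with the configured truth.

    Per replicate the pipeline estimate of (a) the cohort mean proportion of
    overuse days without review within 48 h and (b) the severe-exacerbation
    rate ratio is recorded, alongside a ground-truth exacerbation count read
    from the generator's own bookkeeping. Returns the per-replicate frame
    and a summary with mean estimates and biases (rate-ratio bias is against
    the configured rate ratio; the proportion's reference is the
    Monte-Carlo mean of the truth-side computation, since stand-down
    protection makes the realised proportion lower than one minus the
    per-day review probability).
    """
    config = config or SyntheticCohortConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        tables, truth = generate_cohort(config, seed=rep_seed, return_truth=True)
        cohort = load_events(tables["actuations"], tables["reviews"], tables["ocs"],
                             tables["participants"])
        days = aggregate_days(cohort)
        classified = classify_days(days, cohort.participants, config.thresholds)
        outcomes = link_reviews(classified, cohort.reviews, levels=(level,))
        summary = count_unreviewed_days(outcomes, level)
        mean_prop = float(summary["proportion_unreviewed"].mean())

        eps = build_episodes(cohort.ocs_courses)
        ep_counts = eps.groupby("participant_id").size()
        parts = cohort.participants
        counts = {}
        for arm in ARMS:
            arm_ids = parts.loc[parts["arm"] == arm, "participant_id"]
            counts[arm] = ep_counts.reindex(arm_ids).fillna(0).to_numpy()
        rr = rate_ratio(counts[SMART], config.n_days, counts[STANDARD], config.n_days)
        true_counts = {arm: truth[arm]["n_exacerbations"] for arm in ARMS}
        rows.append(
            {
                "replicate": rep,
                "seed": rep_seed,
                "mean_unreviewed_proportion": mean_prop,
                "rate_ratio_estimate": rr.estimate,
                "true_smart_exacerbations": int(true_counts[SMART].sum()),
                "true_standard_exacerbations": int(true_counts[STANDARD].sum()),
            }
        )
    per_rep = pd.DataFrame(rows)
    configured = config.configured_exacerbation_rate_ratio
    summary = {
        "configured_rate_ratio": configured,
        "mean_rate_ratio_estimate": float(per_rep["rate_ratio_estimate"].mean()),
        "rate_ratio_bias": float(per_rep["rate_ratio_estimate"].mean() - configured),
        "mean_unreviewed_proportion": float(per_rep["mean_unreviewed_proportion"].mean()),
        "implied_unreviewed_upper_bound": 1.0 - config.review_probability_per_overuse_episode,
        "n_replicates": n_replicates,
    }
    return per_rep, summary
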