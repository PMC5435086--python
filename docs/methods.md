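# Methods

## The analysis problem

In high-risk adult asthma, action plans tell patients to obtain medical
review once reliever (beta-agonist) use crosses a daily limit. Electronic
inhaler monitors time-stamp every actuation, so for a monitored two-arm
trial — SMART (one budesonide/formoterol inhaler for both maintenance and
relief) versus Standard (fixed-dose budesonide/formoterol plus a salbutamol
reliever) — one can ask, day by day, whether overuse was followed by a
medical review within 48 hours, and how medication use evolves around
severe exacerbations. This package implements that analysis as a tested,
reusable pipeline over four delimited event tables (participants,
actuations, reviews, systemic-corticosteroid courses), plus a synthetic
cohort generator so every stage runs at desk scale.

## Day classification

The actuation stream is resolved into per-participant calendar-day totals
(midnight-to-midnight in one study-local timezone; days without events are
explicit zeros so proportions have an exposure-day denominator). Overuse
levels are strict per-day cut-offs at 1x, 1.5x and 2x the action-plan
limit:

* SMART: total budesonide/formoterol actuations > 12 / 16 / 20 (equivalently
  > 8 / 12 / 16 in excess of the four scheduled maintenance actuations);
* Standard: salbutamol actuations > 16 / 24 / 32, with budesonide/formoterol
  reliever use in this arm deliberately ignored (this understates
  Standard-arm overuse, mirroring how the outcome is defined).

Flags nest (extreme ⊂ marked ⊂ high). SMART classification uses the day's
*total* rather than total minus maintenance actually taken, because the
total-based reading stays well defined under imperfect maintenance
adherence; a `smart_mode="excess"` escape hatch subtracts the scheduled
maintenance count, which is equivalent at the default settings.

## Review linkage and the stand-down ledger

An overuse ("index") day is *reviewed* if a medical review falls on that
day or the next (the 48-hour rule; one rule for both arms). When a review
is linked to an index day, a stand-down applies: overuse on the index day,
the review day and the 7 following days is not counted as
overuse-without-review; any further review attended inside an open
stand-down restarts the 7-day clock, so windows chain. Operationally, per
participant and per level:

1. a review is *linked* if it falls on a level-specific overuse day or the
   day after;
2. scanning reviews in date order, a linked review opens `[r, r+7]`; any
   review inside an open window (linked or not) extends it through its own
   date + 7;
3. linked index days are themselves protected.

A day counts as "without medical review within 48 h" iff it is neither
reviewed nor protected. The ledger is built separately per level because
index days — hence linked reviews — are level-specific; a consequence worth
knowing is that a review linked only to a high-not-marked day opens no
stand-down window in the marked-level ledger. Reviews before any overuse
day open no window (no retroactive excusal except through a still-open
window). The per-participant proportion of unreviewed overuse days uses all
overuse days at the level as denominator (stand-down-protected days
included) and is undefined — excluded from cohort means — for participants
with none.

The test suite checks the ledger against an independently written
brute-force evaluation (fixed-point interval expansion over all reviews) on
10,000 random fixtures, plus a monotonicity property: adding a review never
increases anyone's unreviewed count.

## Severe-exacerbation episodes and peri-exacerbation windows

A severe exacerbation is a systemic-corticosteroid course of ≥ 3 therapy
days; courses separated by fewer than 7 days (last day of the earlier to
first day of the later) merge into one episode anchored at the earliest
start (Day 0). Courses are merged first, then the ≥ 3-day requirement is
applied to the merged therapy days; overlapping courses merge with a
warning. Medication use is profiled over offsets −14…+14 around Day 0,
with offsets outside the monitoring period absent (not zero). For repeat
exacerbations, an episode whose Day 0 falls within 28 days after the
previous retained episode's Day 0 is excluded from the window analysis
(reason `overlap_28d`) but still counts as an exacerbation event; episodes
without usable monitor data are excluded with reason `no_monitor_data` and
still anchor the interval rule. "Pre-exacerbation" means offsets −14…−1
strictly; Day 0 itself is "post".

Dose dumping — ≥ 100 actuations of one medication within any 3-hour span —
is flagged by a sliding window anchored at each event, with overlapping
qualifying windows coalesced into one flag; flagged days stay in the
profiles. The detector is checked against an O(n²) pair scan on random
event streams. Window profiles report per-offset medians and quartiles
(linear-interpolated, the pandas default).

## Between-arm statistics

Binary outcomes (at least one overuse episode) use a 2×2 relative risk with
a Wald interval on the log scale, SE = sqrt(1/a − 1/n_a + 1/b − 1/n_b), and
a Haldane–Anscombe 0.5 correction (flagged) when an arm has zero events.
Count outcomes (overuse days, unreviewed days, exacerbations) use Poisson
regression of per-participant counts on arm with an offset for log exposure
days and quasi-Poisson over-dispersion: standard errors scaled by
sqrt(Pearson χ²/df). With equal exposures the point estimate is the ratio
of mean counts. Exposure is each participant's monitored days
(monitor_end − monitor_start + 1), the only exposure measure derivable from
the inputs. Wald intervals are used throughout (they reproduce the
published contingency results to 2 decimal places); no multiplicity
adjustment is applied.

With the published counts, the equal-exposure exacerbation rate ratio is
(35/151)/(66/152) = 0.534; the published 0.54 presumably reflects the
trial's real, unpublished per-participant exposure adjustment, so only the
printed relative risks are reproduced exactly.

## Synthetic cohort generator

The generator emulates the monitored trial's statistical structure: 151 +
152 participants, 168 monitored days, and per-day counts built from

* maintenance: Binomial(4, 0.8) actuations/day (imperfect adherence);
* baseline reliever: negative binomial, mean 2/day, shape k = 10 — modest
  overdispersion with a tail that produces occasional isolated high-use
  days;
* overuse blocks: a negative-binomial number of blocks per participant
  (means 1.5 SMART / 2.7 Standard, shapes 0.5 / 0.25, so roughly half of
  each arm has ≥ 1 high-use day while Standard accrues more total days in a
  longer-tailed distribution), geometric durations with mean 3 days; each
  block day draws a magnitude (high 0.5 / marked 0.2 / extreme 0.3) and a
  reliever count from that magnitude's band;
* exacerbations: Poisson per participant at rates 35/151 (SMART) and 66/152
  (Standard), each anchoring a 3–7-day corticosteroid course and an
  arm-specific additive use ramp (SMART rising from −5 d; Standard variable
  from −14 d with a spike at −1 d; both back to baseline by ≈ +10 d), sized
  so median peri-exacerbation day totals peak around 11–13 actuations —
  typical exacerbation days sit at or just under the overuse thresholds;
* reviews: care-seeking is decided once per overuse episode (maximal run of
  consecutive high-threshold days) with probability 0.06, attended at a lag
  of 0–1 days, and reconsidered if overuse persists beyond the stand-down
  coverage of an earlier review. Reviews also occur at Day 0 of a
  corticosteroid course with probability 0.25 (action plans permitted
  self-started prednisone, so most courses need not coincide with an
  attendance) and as sporadic background attendances (0.4 per participant
  per period).

Per-episode (rather than per-day-independent) care-seeking is the detail
that makes the configured probability meaningful: a review's stand-down
covers the rest of a clustered run, so per-day firing at 0.06 would drive
the realized unreviewed proportion far below 0.94, whereas one decision per
episode leaves the cohort mean just below 1 − 0.06 (Monte-Carlo mean ≈ 0.90
at the high level once exacerbation-linked and background reviews are
included, 0.93–0.96 at marked/extreme — the same 0.90–0.94 band the
monitored trial reported).

Day counts are expanded into second-resolution timestamps uniformly within
each day; exacerbation anchors are drawn ≥ 14 days apart so each drawn
event remains a distinct episode under the 7-day course-separation rule
(generated counts are exact ground truth for recovery experiments) while
pairs within 28 days still occur and exercise the window-exclusion rule.
Generation is byte-reproducible from (config, seed).

What the generator does *not* emulate: seasonal or weekday structure,
within-day use patterns (timestamps are uniform, so dose dumping never
arises by default), device failures or missing monitor days (every
in-period day is treated as observed), withdrawal/loss to follow-up
(exposure is complete for everyone), and behavioural correlation between
adherence and exacerbation risk. Passing tests therefore demonstrate the
pipeline's correctness under the trial's statistical shapes, not robustness
to real-world data pathology.

## Recovery experiments and test scales

`recovery_experiment` regenerates a cohort per replicate, runs the full
pipeline (CSV semantics included), and compares recovered quantities with
the configured truth: the severe-exacerbation rate ratio (configured
(35/151)/(66/152) ≈ 0.53) is recovered with mean bias ≈ −0.002 over 200
replicates, and the cohort mean unreviewed proportion lands near 0.90. The
default test run uses 10,000 random ledger fixtures, 150 random dose-dump
streams, 1,500 coverage simulations for the quasi-Poisson interval and 200
full-pipeline replicates — about three minutes end to end on one CPU.

## Numerical and degenerate-input conventions

Percentages are integers rounded half-up; ratios are reported at full
precision in machine outputs and 2 decimals in rendered summaries.
Quantiles use linear interpolation. Zero-event arms trigger flagged
continuity corrections rather than errors; participants with no overuse
days contribute counts of 0 and undefined proportions; empty review tables
yield proportions of exactly 1. Ties for the day of maximal use within a
window resolve to the earliest offset. Out-of-period events are rejected
with a per-row report rather than failing the run; structurally invalid
rows (unknown ids, inverted date ranges, a salbutamol event for a SMART
participant, malformed timestamps) abort with a report naming the rows.

## Known limitations

* The stand-down ledger is level-specific by construction; cross-level
  interactions (a review triggered by high-only use) are handled exactly as
  the definitional rules imply, which can look surprising at stricter
  levels.
* The quasi-Poisson interval is Wald-based; with very sparse counts (total
  events < ~10 per arm) a score or exact interval would behave better.
* `extract_window` truncates at monitoring bounds but does not model
  missing monitor days inside the period.
* The generator's review stream contains no non-asthma attendances beyond
  the background rate, and its exposure is identical across participants.
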