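"""Between-arm statistics: relative risks and quasi-Poisson rate ratios.

Binary outcomes ("at least one episode of overuse") are compared by simple
2x2 contingency analysis expressed as a relative risk with a Wald interval
on the log scale:

    RR = (a/n_a) / (b/n_b),
    SE(log RR) = sqrt(1/a - 1/n_a + 1/b - 1/n_b).

Count outcomes (days of overuse, exacerbations) are compared by Poisson
regression of per-participant counts on arm with an offset for the log days
of treatment exposure and an over-dispersion adjustment: the covariance is
scaled by the Pearson chi-square / df (quasi-Poisson), so the point estimate
is the maximum-likelihood rate ratio while the interval widens with the
observed extra-Poisson variation. With equal exposures the point estimate
reduces to the ratio of mean counts. No multiplicity adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

RELATIVE_RISK_WALD = "RELATIVE_RISK_WALD"
QUASIPOISSON_RATE_RATIO = "QUASIPOISSON_RATE_RATIO"

Z95 = sps.norm.ppf(0.975)


@dataclass(frozen=True)
class TwoByTwo:
    """Participants with/without the outcome by arm (A = SMART, B = Standard)."""

    events_a: int
    n_a: int
    events_b: int
    n_b: int

    def __post_init__(self):
        if min(self.events_a, self.events_b) < 0 or min(self.n_a, self.n_b) <= 0:
            raise ValueError("counts must be non-negative and denominators positive")
        if self.events_a > self.n_a or self.events_b > self.n_b:
            raise ValueError("events cannot exceed denominators")


@dataclass(frozen=True)
class ArmComparison:
    """A between-arm ratio with its 95% Wald interval and two-sided p-value."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    dispersion: float | None = None
    continuity_corrected: bool = False


def relative_risk(table: TwoByTwo) -> ArmComparison:
    """Relative risk A vs B with 95% Wald CI on the log scale.

    If either arm has zero events, 0.5 is added to every cell of the 2x2
    table (Haldane-Anscombe) and the result is flagged
    ``continuity_corrected``.
    """
    a, na, b, nb = table.events_a, table.n_a, table.events_b, table.n_b
    corrected = a == 0 or b == 0
    if corrected:
        a, b = a + 0.5, b + 0.5
        na, nb = na + 1.0, nb + 1.0
    rr = (a / na) / (b / nb)
    se = np.sqrt(1.0 / a - 1.0 / na + 1.0 / b - 1.0 / nb)
    log_rr = np.log(rr)
    z = log_rr / se
    return ArmComparison(
        estimate=float(rr),
        ci_low=float(np.exp(log_rr - Z95 * se)),
        ci_high=float(np.exp(log_rr + Z95 * se)),
        p_value=float(2.0 * sps.norm.sf(abs(z))),
        method=RELATIVE_RISK_WALD,
        continuity_corrected=corrected,
    )


def rate_ratio(counts_a, exposure_a, counts_b, exposure_b,
               overdispersion: bool = True) -> ArmComparison:
    """Rate ratio A vs B from per-participant counts with an exposure offset.

    Fits ``count ~ arm`` with a log link and ``offset = log(exposure)``.
    With ``overdispersion=True`` (default) the standard errors are scaled by
    sqrt(Pearson chi-square / df); with ``False`` the fit is plain Poisson,
    whose Wald interval matches the closed form
    ``exp(log(C_a E_b / (C_b E_a)) +- 1.96 sqrt(1/C_a + 1/C_b))`` on the
    aggregate counts. If one arm's counts are all zero, a continuity-
    corrected aggregate estimate (0.5 added to each arm total) is returned
    with a flag.
    """
    ca = np.asarray(counts_a, dtype=float)
    cb = np.asarray(counts_b, dtype=float)
    ea = np.broadcast_to(np.asarray(exposure_a, dtype=float), ca.shape)
    eb = np.broadcast_to(np.asarray(exposure_b, dtype=float), cb.shape)
    if len(ca) < 2 or len(cb) < 2:
        raise ValueError("need at least two participants per arm")
    if (ea <= 0).any() or (eb <= 0).any():
        raise ValueError("exposures must be positive")

    if ca.sum() == 0 or cb.sum() == 0:
        Ca, Cb = ca.sum() + 0.5, cb.sum() + 0.5
        est = (Ca / ea.sum()) / (Cb / eb.sum())
        se = np.sqrt(1.0 / Ca + 1.0 / Cb)
        log_est = np.log(est)
        return ArmComparison(
            estimate=float(est),
            ci_low=float(np.exp(log_est - Z95 * se)),
            ci_high=float(np.exp(log_est + Z95 * se)),
            p_value=float(2.0 * sps.norm.sf(abs(log_est / se))),
            method=QUASIPOISSON_RATE_RATIO,
            continuity_corrected=True,
        )

    y = np.concatenate([ca, cb])
    arm = np.concatenate([np.ones_like(ca), np.zeros_like(cb)])
    X = sm.add_constant(arm)
    offset = np.log(np.concatenate([ea, eb]))
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    res = model.fit(scale="X2" if overdispersion else 1.0)
    coef = res.params[1]
    se = res.bse[1]
    return ArmComparison(
        estimate=float(np.exp(coef)),
        ci_low=float(np.exp(coef - Z95 * se)),
        ci_high=float(np.exp(coef + Z95 * se)),
        p_value=float(res.pvalues[1]),
        method=QUASIPOISSON_RATE_RATIO,
        dispersion=float(res.scale) if overdispersion else 1.0,
    )


def proportion_summary(per_participant_proportions) -> dict:
    """Descriptive summary (mean, SD, median, IQR, range) over participants.

    NaN entries — participants with no overuse day, whose proportion is
    undefined — are dropped before summarising.
    """
    p = pd.Series(per_participant_proportions, dtype=float).dropna()
    if p.empty:
        return {"n": 0, "mean": np.nan, "sd": np.nan, "median": np.nan,
                "q1": np.nan, "q3": np.nan, "min": np.nan, "max": np.nan}
    return {
        "n": int(p.size),
        "mean": float(p.mean()),
        "sd": float(p.std(ddof=1)) if p.size > 1 else 0.0,
        "median": float(p.median()),
        "q1": float(p.quantile(0.25)),
        "q3": float(p.quantile(0.75)),
        "min": float(p.min()),
        "max": float(p.max()),
    }
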