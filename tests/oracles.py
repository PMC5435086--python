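"""Independent brute-force reference implementations used only by tests.

These recompute the stand-down protection and dose-dumping rules from first
principles (interval chaining by fixed-point expansion; an O(n^2) pair scan)
so the production algorithms can be checked against a second, structurally
different derivation.
"""

from __future__ import annotations

import numpy as np


def brute_force_review_outcomes(overuse_days, review_days, standdown: int = 7,
                                window: int = 2):
    """First-principles evaluation of the 48-h rule and stand-down protection.

    Works on integer day numbers. For every linked review (one falling on an
    overuse day or the day after), a protection interval opens and is
    expanded to a fixed point by any review landing inside it. Returns
    ``{day: (reviewed_within_window, counted_as_unreviewed)}``.
    """
    overuse = sorted(set(int(d) for d in overuse_days))
    reviews = sorted(set(int(r) for r in review_days))
    over_set = set(overuse)
    linked = [r for r in reviews if any(r - k in over_set for k in range(window))]

    protected: set = set()
    for r0 in linked:
        end = r0 + standdown
        changed = True
        while changed:
            changed = False
            for r in reviews:
                if r0 < r <= end and r + standdown > end:
                    end = r + standdown
                    changed = True
        protected.update(range(r0, end + 1))

    out = {}
    rev_set = set(reviews)
    for d in overuse:
        reviewed = any(d + k in rev_set for k in range(window))
        counted = not reviewed and d not in protected
        out[d] = (reviewed, counted)
    return out


def brute_force_dump_intervals(times_ns, threshold: int = 100,
                               window_ns: int = 3 * 3600 * 10**9):
    """O(n^2) pair scan for dose dumping on sorted int64 timestamps.

    Every pair (i, j) with t_j - t_i <= window and j - i + 1 >= threshold
    marks the interval [t_i, t_j]; overlapping marked intervals merge.
    Returns a list of (start_ns, end_ns, max_count) tuples.
    """
    t = np.sort(np.asarray(times_ns, dtype=np.int64))
    n = len(t)
    if n < threshold:
        return []
    diff = t[None, :] - t[:, None]          # diff[i, j] = t_j - t_i
    ii, jj = np.nonzero((diff >= 0) & (diff <= window_ns))
    counts = jj - ii + 1
    qual = counts >= threshold
    ii, jj, counts = ii[qual], jj[qual], counts[qual]
    if len(ii) == 0:
        return []
    order = np.argsort(t[ii], kind="stable")
    merged = []
    for i, j, c in zip(ii[order], jj[order], counts[order]):
        if merged and t[i] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], t[j])
            merged[-1][2] = max(merged[-1][2], int(c))
        else:
            merged.append([t[i], t[j], int(c)])
    return [tuple(m) for m in merged]
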