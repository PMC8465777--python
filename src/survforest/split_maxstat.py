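"""Maximally-selected-rank-statistics splitting.

Each node member gets a log-rank score ``a_i`` (see
:func:`survforest._survival.logrank_scores`).  For a candidate variable
``X_j`` and cutpoint ``c`` the standardized two-sample statistic is

    S(X_j, c) = ( sum_{x_ji <= c} a_i  -  n_l abar )
                / sqrt( n_l n_r S_a^2 / n )

with ``abar`` and ``S_a^2`` the sample mean and (n-1)-denominator sample
variance of the scores — this makes the denominator the exact
permutation standard deviation of the left-child score sum.  In one pass
over the cutpoints of the admissible quantile band
``minprop <= n_l/n <= 1 - minprop`` the rule records each candidate's
maximum ``M_j = max_c |S|`` and a p-value for that maximum via a
Lausen–Schumacher-type improved-Bonferroni approximation.  The
smallest-p candidate wins; the split is made at its recorded cutpoint
only if the Bonferroni-adjusted p-value over the tested candidates falls
below ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._split import SplitDecision, order_levels_by_score, prefix_level_mask
from ._survival import logrank_scores


def standardized_statistic(a, left):
    """S for a single candidate split given scores ``a`` and a boolean
    left-membership vector; NaN if undefined (empty child or zero score
    variance)."""
    a = np.asarray(a, dtype=float)
    left = np.asarray(left, dtype=bool)
    n = a.size
    n_l = int(left.sum())
    if n_l == 0 or n_l == n:
        return float("nan")
    s2 = a.var(ddof=1)
    if s2 <= 0:
        return float("nan")
    n_r = n - n_l
    return (a[left].sum() - n_l * a.mean()) / np.sqrt(n_l * n_r * s2 / n)


def lausen92_pvalue(b, eps_lo, eps_hi):
    """Approximate P(max |S| > b) over the quantile band [eps_lo, eps_hi]
    for a standardized Brownian-bridge-type maximally selected statistic
    (Lausen & Schumacher's large-sample approximation)."""
    if b <= 0:
        return 1.0
    phi = stats.norm.pdf(b)
    span = np.log((1.0 - eps_lo) * eps_hi / ((1.0 - eps_hi) * eps_lo))
    p = 4.0 * phi / b + phi * (b - 1.0 / b) * span
    return float(min(1.0, p))


@dataclass(frozen=True)
class MaxstatResult:
    """Best cutpoint of one candidate with its maximum statistic and the
    multiplicity-aware p-value of that maximum."""

    threshold: float
    level_mask: int
    statistic: float
    p_value: float


def maxstat_over_cutpoints(x, a, minprop=0.1, min_child_size=1, kind=0):
    """Scan the admissible cutpoints of one candidate.

    Numeric/ordered candidates are scanned along their sorted values;
    unordered factors (``kind = k >= 2``) are score-ordered first and
    scanned along prefix level sets.  Returns a :class:`MaxstatResult`
    or ``None`` when no admissible cutpoint exists.
    """
    a = np.asarray(a, dtype=float)
    n = a.size
    s2 = a.var(ddof=1)
    if s2 <= 0:
        return None
    if kind >= 2:
        order_levels, g = order_levels_by_score(x, int(kind), a)
        xv = g.astype(float)
    else:
        order_levels, xv = None, np.asarray(x, dtype=float)
    order = np.argsort(xv, kind="stable")
    xs = xv[order]
    boundary = np.flatnonzero(xs[:-1] < xs[1:])
    if boundary.size == 0:
        return None
    n_l = boundary + 1.0
    lo = max(min_child_size, int(np.ceil(minprop * n)))
    hi = min(n - min_child_size, int(np.floor((1.0 - minprop) * n)))
    keep = (n_l >= lo) & (n_l <= hi)
    if not keep.any():
        return None
    boundary = boundary[keep]
    n_l = n_l[keep]
    csum = np.cumsum(a[order])[boundary]
    stat = (csum - n_l * a.mean()) / np.sqrt(n_l * (n - n_l) * s2 / n)
    best = int(np.argmax(np.abs(stat)))
    m = float(abs(stat[best]))
    n_cuts = boundary.size
    p_point = 2.0 * stats.norm.sf(m)
    if n_cuts == 1:
        p = p_point
    else:
        eps_lo = n_l[0] / n
        eps_hi = n_l[-1] / n
        p = max(p_point, min(1.0, lausen92_pvalue(m, eps_lo, eps_hi), n_cuts * p_point))
    b = boundary[best]
    if order_levels is not None:
        n_left = int(np.searchsorted(np.unique(xv), 0.5 * (xs[b] + xs[b + 1]), side="right"))
        mask = prefix_level_mask(order_levels, n_left)
        return MaxstatResult(float("nan"), mask, m, p)
    return MaxstatResult(0.5 * (xs[b] + xs[b + 1]), 0, m, p)


class MaxstatSplitter:
    """Split rule: smallest maximally-selected p-value, alpha-stopping."""

    needs_alpha = True

    def __init__(self, minprop: float = 0.1, min_child_size: int = 1):
        self.minprop = minprop
        self.min_child_size = min_child_size

    def find_split(self, Xc, cand_kinds, time, event, cand_ids, alpha=0.05, bins=None):
        if event.sum() == 0:
            return None
        a = logrank_scores(time, event)
        if a.var(ddof=1) <= 0:
            return None
        results = []
        for local in range(Xc.shape[1]):
            res = maxstat_over_cutpoints(
                Xc[:, local], a, self.minprop, self.min_child_size,
                kind=int(cand_kinds[local]),
            )
            if res is not None:
                results.append((res.p_value, int(cand_ids[local]), res))
        if not results:
            return None
        p_min, j_star, res = min(results, key=lambda r: (r[0], r[1]))
        p_adj = min(1.0, p_min * len(results))
        if p_adj >= alpha:
            return None
        return SplitDecision(j_star, res.threshold, res.level_mask, res.statistic, p_adj)
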