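"""Conditional-inference splitting (two-step permutation-test rule).

Step 1 tests, for each candidate covariate, the partial null hypothesis
of independence between the survival response and that covariate with a
linear rank statistic

    T_j = sum_i g_j(x_ji) h_i

where ``h`` are the log-rank scores of the node's responses and ``g`` is
the identity for numeric/ordered covariates (an induced level ordering
for unordered factors).  ``T_j`` is standardized by its exact
conditional (permutation) mean and variance given the observed ``g`` and
``h`` values,

    mu_j     = (sum g)(sum h) / n
    sigma2_j = n/(n-1) V_h sum g^2  -  1/(n-1) V_h (sum g)^2,

with ``V_h`` the mean-square deviation of ``h``, and referred to the
standard normal.  If no Bonferroni-adjusted p-value falls below
``alpha`` the node stops; otherwise the smallest-p variable is selected.

Step 2 picks the cutpoint of the selected variable by maximising the
absolute standardized two-sample statistic ``sum_{x<=c} h_i`` (the
``g = I(x<=c)`` special case of the same linear statistic).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ._split import SplitDecision, order_levels_by_score, prefix_level_mask
from ._survival import logrank_scores


def permutation_moments(g, h):
    """Conditional mean and variance of ``sum g_i h_perm(i)`` under
    uniformly random permutations of ``h``."""
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    n = g.size
    v_h = np.mean((h - h.mean()) ** 2)
    sg = g.sum()
    mu = sg * h.mean()
    var = n / (n - 1.0) * v_h * np.sum(g * g) - v_h * sg * sg / (n - 1.0)
    return mu, max(var, 0.0)


def association_test(g, h):
    """Standardized linear rank statistic and two-sided normal p-value.

    Returns ``(u, p)`` or ``None`` when the permutation variance is zero
    (constant covariate or constant scores).
    """
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    mu, var = permutation_moments(g, h)
    if var <= 1e-300:
        return None
    u = (np.dot(g, h) - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(u))
    return u, p


def best_split_point(x, h, min_child_size=1):
    """Cutpoint maximising the absolute standardized two-sample statistic.

    Returns ``(threshold, statistic)`` or ``None`` if no admissible
    cutpoint exists.  Ties in the statistic resolve to the smallest
    cutpoint.
    """
    x = np.asarray(x, dtype=float)
    h = np.asarray(h, dtype=float)
    n = x.size
    order = np.argsort(x, kind="stable")
    xs = x[order]
    boundary = np.flatnonzero(xs[:-1] < xs[1:])
    boundary = boundary[(boundary + 1 >= min_child_size) & (n - boundary - 1 >= min_child_size)]
    if boundary.size == 0:
        return None
    csum = np.cumsum(h[order])[boundary]
    n_l = boundary + 1.0
    n_r = n - n_l
    v_h = np.sum((h - h.mean()) ** 2) / (n - 1.0)
    if v_h <= 1e-300:
        return None
    stat = (csum - n_l * h.mean()) / np.sqrt(n_l * n_r * v_h / n)
    best = int(np.argmax(np.abs(stat)))
    b = boundary[best]
    return 0.5 * (xs[b] + xs[b + 1]), float(stat[best])


class ConditionalSplitter:
    """Split rule: permutation association test, then cutpoint search."""

    needs_alpha = True

    def __init__(self, min_child_size: int = 1):
        self.min_child_size = min_child_size

    def find_split(self, Xc, cand_kinds, time, event, cand_ids, alpha=0.05, bins=None):
        if event.sum() == 0:
            return None
        h = logrank_scores(time, event)
        if np.ptp(h) <= 1e-300:
            return None
        results = []  # (p, j, u, order or None)
        for local in range(Xc.shape[1]):
            j = int(cand_ids[local])
            x = Xc[:, local]
            k_levels = int(cand_kinds[local])
            if k_levels >= 2:
                order, g = order_levels_by_score(x, k_levels, h)
                g = g.astype(float)
            else:
                order, g = None, x
            if np.ptp(g) <= 0:
                continue
            res = association_test(g, h)
            if res is None:
                continue
            u, p = res
            results.append((p, j, u, order, g))
        if not results:
            return None
        n_tested = len(results)
        p_min, j_star, u_star, order, g = min(results, key=lambda r: (r[0], r[1]))
        p_adj = min(1.0, p_min * n_tested)
        if p_adj >= alpha:
            return None
        cut = best_split_point(g, h, self.min_child_size)
        if cut is None:
            return None
        threshold, _ = cut
        if order is not None:
            n_left = int(np.searchsorted(np.unique(g), threshold, side="right"))
            mask = prefix_level_mask(order, n_left)
            return SplitDecision(j_star, float("nan"), mask, float(u_star), p_adj)
        return SplitDecision(j_star, float(threshold), 0, float(u_star), p_adj)
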