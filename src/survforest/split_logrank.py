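"""Log-rank splitting (the classic random-survival-forest rule).

The node statistic for splitting variable ``X_j`` at cutpoint ``c`` is

    L(X_j, c) = sum_k (d_kl - Y_kl d_k / Y_k)
                / sqrt( sum_k (Y_kl/Y_k)(1 - Y_kl/Y_k)
                        ((Y_k - d_k)/(Y_k - 1)) d_k )

over the node's distinct event times ``t_k`` with ``d``/``Y`` the event
and at-risk counts and the ``l`` subscript the left child.  |L| measures
node separation; the rule maximises it jointly over all candidate
variables and all of their cutpoints.  Terms with ``Y_k = 1`` have
undefined variance and contribute zero.  No hypothesis test is attached:
tree depth is limited by node-size constraints only.

The cutpoint scan is a compiled prefix sweep: rows enter the left child
one at a time in x-sorted order and the statistic's numerator and
variance are updated incrementally, so one candidate costs
``O(sum_i r_i)`` with ``r_i`` the number of event-time bins row ``i`` is
at risk in.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._split import (
    EXHAUSTIVE_FACTOR_LEVELS,
    SplitDecision,
    order_levels_by_score,
    prefix_level_mask,
)
from ._survival import logrank_scores


@njit(cache=True)
def _best_numeric_split(Xc, ri, ei, w1, ck, Yk, min_child):
    """Best log-rank split over all numeric candidate columns of ``Xc``.

    ``ri[i]`` is the number of event-time bins row ``i`` is at risk in
    (bins ``k < ri[i]``), ``ei[i]`` its event bin (-1 if censored),
    ``w1[k] = d_k/Y_k`` and ``ck[k] = d_k (Y_k - d_k)/(Y_k - 1)`` (0 at
    ``Y_k = 1``).  Ties resolve to the first column (candidates arrive in
    ascending variable order) and the smallest cutpoint.  Returns
    ``(col, threshold, L)`` with ``col = -1`` when no admissible split
    exists.
    """
    n, m = Xc.shape
    K = w1.shape[0]
    Yl = np.zeros(K)
    best_j = -1
    best_thr = np.nan
    best_stat = 0.0
    best_abs = 0.0
    for j in range(m):
        order = np.argsort(Xc[:, j])
        for k in range(K):
            Yl[k] = 0.0
        s_num = 0.0
        s_den = 0.0
        for i in range(n - 1):
            idx = order[i]
            r = ri[idx]
            for k in range(r):
                p_old = Yl[k] / Yk[k]
                Yl[k] += 1.0
                p_new = Yl[k] / Yk[k]
                s_num -= w1[k]
                s_den += ck[k] * ((p_new - p_new * p_new) - (p_old - p_old * p_old))
            if ei[idx] >= 0:
                s_num += 1.0
            x_lo = Xc[order[i], j]
            x_hi = Xc[order[i + 1], j]
            if x_lo < x_hi and i + 1 >= min_child and n - i - 1 >= min_child and s_den > 0.0:
                stat = s_num / np.sqrt(s_den)
                if abs(stat) > best_abs + 1e-12:
                    best_abs = abs(stat)
                    best_stat = stat
                    best_j = j
                    best_thr = 0.5 * (x_lo + x_hi)
    return best_j, best_thr, best_stat


def _node_bins(time, event, bins=None):
    """Node-level event-time bins: per-row at-risk/event bin indices plus
    ``(Y_k, d_k)`` counts.

    With ``bins`` given (precomputed global-grid indices ``ri_g``/``ei_g``
    of the node members), everything is integer bookkeeping; otherwise
    the bins are built from the node's raw times.
    """
    n = time.size if time is not None else bins[0].size
    if bins is None:
        ut = np.unique(time[event == 1])
        if ut.size == 0:
            return None
        ri = np.searchsorted(ut, time, side="right").astype(np.int64)
        ei = np.where(event == 1, np.searchsorted(ut, time), -1).astype(np.int64)
        K = ut.size
    else:
        ri_g, ei_g = bins
        ubins = np.unique(ei_g[ei_g >= 0])
        if ubins.size == 0:
            return None
        ri = np.searchsorted(ubins, ri_g - 1, side="right").astype(np.int64)
        ei = np.where(ei_g >= 0, np.searchsorted(ubins, ei_g), -1).astype(np.int64)
        K = ubins.size
    hist = np.bincount(ri, minlength=K + 1)
    Yk = (n - np.cumsum(hist)[:K]).astype(float)
    dk = np.bincount(ei[ei >= 0], minlength=K).astype(float)
    return ri, ei, Yk, dk


def logrank_statistic(time, event, left):
    """Standardized two-sample log-rank statistic for one candidate split.

    ``left`` is a boolean membership vector.  Returns NaN when the
    statistic is undefined (empty child, no events, zero variance).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    left = np.asarray(left, dtype=bool)
    if left.all() or not left.any():
        return float("nan")
    nb = _node_bins(time, event)
    if nb is None:
        return float("nan")
    ri, ei, Yk, dk = nb
    K = Yk.size
    Ylk = (ri[left, None] > np.arange(K)[None, :]).sum(axis=0).astype(float)
    dlk = np.bincount(ei[left & (ei >= 0)], minlength=K).astype(float)
    num = np.sum(dlk - Ylk * dk / Yk)
    ck = np.where(Yk > 1, dk * (Yk - dk) / np.maximum(Yk - 1, 1), 0.0)
    p = Ylk / Yk
    den2 = np.sum(p * (1.0 - p) * ck)
    if den2 <= 0:
        return float("nan")
    return num / np.sqrt(den2)


class LogrankSplitter:
    """Split rule: maximise |L| over all candidates and cutpoints."""

    needs_alpha = False

    def __init__(self, min_child_size: int = 1):
        self.min_child_size = min_child_size

    def find_split(self, Xc, cand_kinds, time, event, cand_ids, alpha=None, bins=None):
        """``Xc`` holds the candidate columns (ascending variable order);
        the returned decision carries the global variable id."""
        nb = _node_bins(time, event, bins)
        if nb is None:
            return None
        ri, ei, Yk, dk = nb
        w1 = dk / Yk
        ck = np.where(Yk > 1, dk * (Yk - dk) / np.maximum(Yk - 1, 1), 0.0)
        n = ri.size
        numeric = np.flatnonzero(cand_kinds == 0)
        best = None
        best_abs = 0.0
        if numeric.size:
            j, thr, stat = _best_numeric_split(
                np.ascontiguousarray(Xc[:, numeric]), ri, ei, w1, ck, Yk,
                self.min_child_size,
            )
            if j >= 0:
                best = SplitDecision(int(cand_ids[numeric[j]]), float(thr), 0, float(stat))
                best_abs = abs(stat)
        scores = None
        for local in np.flatnonzero(cand_kinds > 0):
            x = Xc[:, local]
            k_levels = int(cand_kinds[local])
            if k_levels <= EXHAUSTIVE_FACTOR_LEVELS:
                dec = self._best_factor_split(
                    x, k_levels, ri, ei, Yk, dk, w1, ck, int(cand_ids[local]), n
                )
            else:
                # too many level partitions to enumerate: order levels by
                # mean log-rank score and scan prefix cuts instead
                if scores is None:
                    scores = logrank_scores(time, event)
                order, g = order_levels_by_score(x, k_levels, scores)
                jj, thr, stat = _best_numeric_split(
                    np.ascontiguousarray(g.astype(float)[:, None]), ri, ei, w1, ck, Yk,
                    self.min_child_size,
                )
                if jj < 0:
                    dec = None
                else:
                    n_left = int(np.searchsorted(np.unique(g), thr, side="right"))
                    mask = prefix_level_mask(order, n_left)
                    dec = SplitDecision(int(cand_ids[local]), float("nan"), mask, float(stat))
            if dec is not None and (
                abs(dec.statistic) > best_abs + 1e-12
                or (abs(abs(dec.statistic) - best_abs) <= 1e-12
                    and best is not None and dec.feature < best.feature)
            ):
                best, best_abs = dec, abs(dec.statistic)
        return best

    def _best_factor_split(self, x, k, ri, ei, Yk, dk, w1, ck, feature, n):
        """Exhaustive search over the 2^(k-1)-1 binary level partitions."""
        codes = x.astype(np.int64)
        K = Yk.size
        risk = ri[:, None] > np.arange(K)[None, :]
        Ylev = np.zeros((k, K))
        np.add.at(Ylev, codes - 1, risk.astype(float))
        dlev = np.zeros((k, K))
        ev_rows = ei >= 0
        np.add.at(dlev, (codes[ev_rows] - 1, ei[ev_rows]), 1.0)
        counts = np.bincount(codes - 1, minlength=k).astype(float)
        n_subsets = (1 << (k - 1)) - 1
        subsets = np.arange(1, n_subsets + 1)
        # bit matrix over levels 1..k-1 (level k always stays right)
        B = ((subsets[:, None] >> np.arange(k)[None, :]) & 1).astype(float)
        Yl = B @ Ylev          # (S, K)
        dl = B @ dlev
        n_l = B @ counts
        with np.errstate(invalid="ignore", divide="ignore"):
            numv = np.sum(dl - Yl * (dk / Yk)[None, :], axis=1)
            p = Yl / Yk[None, :]
            den2 = np.sum(p * (1.0 - p) * ck[None, :], axis=1)
            stat = numv / np.sqrt(den2)
        mcs = self.min_child_size
        good = (n_l >= mcs) & (n - n_l >= mcs) & (den2 > 0) & np.isfinite(stat)
        if not good.any():
            return None
        idx = np.flatnonzero(good)
        b = idx[np.argmax(np.abs(stat[idx]))]
        return SplitDecision(feature, float("nan"), int(subsets[b]), float(stat[b]))
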