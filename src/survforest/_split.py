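"""Split-rule contract shared by the three splitting modules.

A split rule looks at one node — the node's covariate rows, times and
events plus the candidate column indices drawn for that node — and
returns a :class:`SplitDecision` or ``None`` (node becomes a leaf).

Covariate kinds are encoded per column as an integer: ``0`` means
numeric / ordered (split as ``x <= c``), ``k >= 2`` means an unordered
factor with levels coded ``1..k`` (split as a level subset, stored as a
bitmask with bit ``level-1`` set for levels sent to the left child).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: number of factor levels up to which the log-rank rule enumerates all
#: binary level partitions; above this, levels are score-ordered instead.
EXHAUSTIVE_FACTOR_LEVELS = 8


@dataclass(frozen=True)
class SplitDecision:
    """Outcome of a node-splitting search.

    ``threshold`` carries the cutpoint for numeric/ordered columns and is
    NaN for factors, where ``level_mask`` holds the left-child level set.
    ``p_value`` is the multiplicity-adjusted p-value for test-based rules
    and NaN for the plain log-rank rule.
    """

    feature: int
    threshold: float
    level_mask: int
    statistic: float
    p_value: float = float("nan")

    @property
    def is_factor_split(self) -> bool:
        return self.level_mask != 0

    def go_left(self, x):
        """Vectorized routing of covariate values ``x`` for this split."""
        x = np.asarray(x)
        if self.is_factor_split:
            codes = np.clip(x.astype(np.int64) - 1, 0, 62)
            return (self.level_mask >> codes) & 1 == 1
        return x <= self.threshold


def order_levels_by_score(x, k, scores):
    """Order factor levels ``1..k`` by their within-node mean score.

    Returns ``(order, g)``: ``order`` lists the levels present in the node
    sorted by mean score (ties by level code), and ``g`` maps each row to
    the 0-based position of its level in that ordering.  This is the
    standard trick that lets rank-statistic machinery treat an unordered
    factor as monotone in an induced ordering.
    """
    codes = x.astype(np.int64)
    counts = np.bincount(codes, minlength=k + 1)[1:]
    sums = np.bincount(codes, weights=scores, minlength=k + 1)[1:]
    present = np.flatnonzero(counts > 0) + 1
    means = sums[present - 1] / counts[present - 1]
    order = present[np.lexsort((present, means))]
    pos = np.empty(k + 1, dtype=np.int64)
    pos[order] = np.arange(order.size)
    return order, pos[codes]


def prefix_level_mask(order, n_left_levels):
    """Bitmask for the first ``n_left_levels`` levels of ``order``."""
    mask = 0
    for lev in order[:n_left_levels]:
        mask |= 1 << (int(lev) - 1)
    return mask
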