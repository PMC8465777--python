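"""Survival-tree machinery: bootstrap, recursive growth with a pluggable
split rule, leaf Nelson–Aalen/Kaplan–Meier estimates and fast routing.

Trees are stored flat (parallel arrays indexed by node id) so that
routing a batch of subjects is a handful of vectorized index operations
per tree level.
"""

from __future__ import annotations

import numpy as np

from ._survival import chf_surv_on_grid


def draw_bootstrap(n, rng):
    """One bootstrap draw: ``n`` indices with replacement plus the
    out-of-bag mask (subjects never drawn; on average a fraction
    ``(1-1/n)^n -> e^-1`` of the sample)."""
    inbag = rng.integers(0, n, size=n)
    oob = np.ones(n, dtype=bool)
    oob[inbag] = False
    return inbag, oob


class SurvivalTree:
    """A grown survival tree in flat-array form.

    ``feature[v] == -1`` marks leaves; internal nodes carry either a
    numeric threshold or a level bitmask (factor splits).  ``seen_mask``
    records the factor levels present at the node during growth and
    ``major_left`` which child received more training members — unseen
    levels at prediction time are routed to the majority child (ties go
    left).
    """

    __slots__ = (
        "feature", "threshold", "level_mask", "seen_mask", "major_left",
        "left", "right", "leaf_id", "leaf_chf", "leaf_surv", "leaf_risk",
        "split_features",
    )

    def __init__(self, nodes, leaf_chf, leaf_surv):
        self.feature = np.asarray(nodes["feature"], dtype=np.int64)
        self.threshold = np.asarray(nodes["threshold"], dtype=float)
        self.level_mask = np.asarray(nodes["level_mask"], dtype=np.int64)
        self.seen_mask = np.asarray(nodes["seen_mask"], dtype=np.int64)
        self.major_left = np.asarray(nodes["major_left"], dtype=bool)
        self.left = np.asarray(nodes["left"], dtype=np.int64)
        self.right = np.asarray(nodes["right"], dtype=np.int64)
        self.leaf_id = np.asarray(nodes["leaf_id"], dtype=np.int64)
        self.leaf_chf = np.asarray(leaf_chf, dtype=float)
        self.leaf_surv = np.asarray(leaf_surv, dtype=float)
        self.leaf_risk = self.leaf_chf.sum(axis=1)
        self.split_features = np.unique(self.feature[self.feature >= 0])

    @property
    def n_nodes(self):
        return self.feature.size

    def apply(self, X):
        """Route each row of ``X`` to a leaf; returns leaf ids."""
        n = X.shape[0]
        node = np.zeros(n, dtype=np.int64)
        while True:
            feat = self.feature[node]
            active = np.flatnonzero(feat >= 0)
            if active.size == 0:
                break
            cur = node[active]
            xv = X[active, feat[active]]
            mask = self.level_mask[cur]
            go_left = np.empty(active.size, dtype=bool)
            num = mask == 0
            if num.any():
                go_left[num] = xv[num] <= self.threshold[cur[num]]
            fac = ~num
            if fac.any():
                codes = np.clip(xv[fac].astype(np.int64) - 1, 0, 62)
                seen = (self.seen_mask[cur[fac]] >> codes) & 1
                gl = ((mask[fac] >> codes) & 1) == 1
                unseen = seen == 0
                if unseen.any():
                    gl[unseen] = self.major_left[cur[fac][unseen]]
                go_left[fac] = gl
            node[active] = np.where(go_left, self.left[cur], self.right[cur])
        return self.leaf_id[node]

    def to_dict(self):
        """JSON-serializable representation (split records + leaf steps)."""
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "level_mask": self.level_mask.tolist(),
            "seen_mask": self.seen_mask.tolist(),
            "major_left": self.major_left.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "leaf_id": self.leaf_id.tolist(),
            "leaf_chf": self.leaf_chf.tolist(),
            "leaf_surv": self.leaf_surv.tolist(),
        }

    @classmethod
    def from_dict(cls, d):
        nodes = {k: d[k] for k in (
            "feature", "threshold", "level_mask", "seen_mask", "major_left",
            "left", "right", "leaf_id")}
        return cls(nodes, d["leaf_chf"], d["leaf_surv"])


def grow_tree(X, time, event, kinds, inbag, splitter, *, mtry,
              min_node_size, min_node_events, alpha, grid, rng,
              ri_grid=None, ei_grid=None):
    """Grow one survival tree on a bootstrap multiset of row indices.

    At each node ``mtry`` candidate columns are drawn without
    replacement and handed to the split rule.  A node becomes a leaf
    when it is too small (``min_node_size``), has too few events
    (``min_node_events``) or the rule finds no admissible split (for
    test-based rules this includes failing the alpha-level stop).  Leaf
    estimates are Nelson–Aalen CHF and Kaplan–Meier survival of the
    node's in-bag members, evaluated on the forest-wide ``grid``.

    ``ri_grid``/``ei_grid`` are optional precomputed per-row grid indices
    (at-risk bin count and event bin) that let node statistics and leaf
    estimates run on integer bins instead of raw times.
    """
    n_features = X.shape[1]
    K = len(grid)
    mtry = min(mtry, n_features)
    nodes = {k: [] for k in (
        "feature", "threshold", "level_mask", "seen_mask", "major_left",
        "left", "right", "leaf_id")}
    leaf_chf, leaf_surv = [], []

    def new_node():
        for k in nodes:
            nodes[k].append(0)
        vid = len(nodes["feature"]) - 1
        nodes["feature"][vid] = -1
        nodes["leaf_id"][vid] = -1
        nodes["threshold"][vid] = np.nan
        return vid

    def make_leaf(vid, members):
        if ri_grid is None:
            chf, surv = chf_surv_on_grid(time[members], event[members], grid)
        else:
            hist = np.bincount(ri_grid[members], minlength=K + 1)
            Y = members.size - np.cumsum(hist)[:K]
            em = ei_grid[members]
            d = np.bincount(em[em >= 0], minlength=K)
            haz = d / np.maximum(Y, 1)
            chf = np.cumsum(haz)
            surv = np.cumprod(1.0 - haz)
        nodes["leaf_id"][vid] = len(leaf_chf)
        leaf_chf.append(chf)
        leaf_surv.append(surv)

    root = new_node()
    stack = [(root, np.asarray(inbag, dtype=np.int64))]
    while stack:
        vid, members = stack.pop()
        n_node = members.size
        n_events = int(event[members].sum())
        if n_node < min_node_size or n_events < min_node_events:
            make_leaf(vid, members)
            continue
        candidates = np.sort(rng.choice(n_features, size=mtry, replace=False))
        bins = None
        if ri_grid is not None:
            bins = (ri_grid[members], ei_grid[members])
        dec = splitter.find_split(
            X[np.ix_(members, candidates)], kinds[candidates],
            time[members], event[members], candidates, alpha=alpha, bins=bins,
        )
        if dec is None:
            make_leaf(vid, members)
            continue
        go_left = dec.go_left(X[members, dec.feature])
        left_members = members[go_left]
        right_members = members[~go_left]
        if left_members.size == 0 or right_members.size == 0:
            make_leaf(vid, members)
            continue
        nodes["feature"][vid] = dec.feature
        nodes["threshold"][vid] = dec.threshold
        nodes["level_mask"][vid] = dec.level_mask
        if dec.is_factor_split:
            seen = 0
            for lev in np.unique(X[members, dec.feature].astype(np.int64)):
                seen |= 1 << (int(lev) - 1)
            nodes["seen_mask"][vid] = seen
        nodes["major_left"][vid] = left_members.size >= right_members.size
        lid, rid = new_node(), new_node()
        nodes["left"][vid] = lid
        nodes["right"][vid] = rid
        stack.append((rid, right_members))
        stack.append((lid, left_members))
    if not leaf_chf:  # cannot happen: root always resolves to >= 1 leaf
        raise RuntimeError("tree grew no leaves")
    return SurvivalTree(nodes, np.vstack(leaf_chf), np.vstack(leaf_surv))
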