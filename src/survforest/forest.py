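"""Scikit-learn-style survival-forest estimators.

All three estimators share the same ensemble machinery — bootstrap
resampling, ``mtry`` candidate draws, Nelson–Aalen leaf estimates,
CHF-averaging aggregation and out-of-bag bookkeeping — and differ only
in the node-splitting rule.  The predicted risk score
(:meth:`SurvivalForestBase.predict`) is the "ensemble mortality": the
sum of the ensemble cumulative hazard over the training event-time grid,
so larger values mean shorter predicted survival.
"""

from __future__ import annotations

import json
import math

import numpy as np
from sklearn.base import BaseEstimator

from ._survival import check_time_event
from .split_conditional import ConditionalSplitter
from .split_logrank import LogrankSplitter
from .split_maxstat import MaxstatSplitter
from .tree import SurvivalTree, draw_bootstrap, grow_tree


class SurvivalForestBase(BaseEstimator):
    """Common survival-forest implementation.

    Parameters
    ----------
    n_trees : int, default 200
        Number of bootstrap trees.
    mtry : int or None
        Candidate covariates drawn at each node; ``None`` means
        ``floor(sqrt(M))``.
    min_node_events, min_node_size : int
        A node with fewer events / members than these becomes a leaf.
    alpha : float, default 0.05
        Significance level for the alpha-stopping of test-based rules
        (ignored by the log-rank rule).
    minprop : float, default 0.1
        Admissible quantile band for maximally selected statistics.
    categorical_features : sequence of int, dict, or None
        Columns to treat as unordered factors with integer level codes
        ``1..k``.  A dict maps column index to its level count; for a
        plain sequence the level count is inferred from the training
        data.
    random_state : int or None
        Seed for the bootstrap and candidate draws.  Per-tree generators
        are spawned from one seed sequence, so results are reproducible
        for a fixed ``(data, params, seed)``.
    """

    _rule = None  # set by subclasses

    def __init__(self, n_trees=200, mtry=None, min_node_events=3,
                 min_node_size=5, alpha=0.05, minprop=0.1,
                 categorical_features=None, random_state=None):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_node_events = min_node_events
        self.min_node_size = min_node_size
        self.alpha = alpha
        self.minprop = minprop
        self.categorical_features = categorical_features
        self.random_state = random_state

    # -- fitting ------------------------------------------------------

    def _make_splitter(self):
        if self._rule == "logrank":
            return LogrankSplitter()
        if self._rule == "conditional":
            return ConditionalSplitter()
        if self._rule == "maxstat":
            return MaxstatSplitter(minprop=self.minprop)
        raise ValueError(f"unknown split rule {self._rule!r}")

    def _resolve_kinds(self, X):
        n_features = X.shape[1]
        kinds = np.zeros(n_features, dtype=np.int64)
        cat = self.categorical_features
        if cat is None:
            return kinds
        if isinstance(cat, dict):
            items = cat.items()
        else:
            items = ((int(j), None) for j in cat)
        for j, k in items:
            col = X[:, j]
            if np.any(col < 1) or np.any(col != np.round(col)):
                raise ValueError(
                    f"factor column {j} must hold integer level codes 1..k"
                )
            kinds[j] = int(k) if k is not None else int(col.max())
            if kinds[j] < 2:
                kinds[j] = 2
        return kinds

    def fit(self, X, y):
        """Grow the forest on covariates ``X`` and survival response ``y``.

        ``y`` may be a scikit-survival structured array, a
        ``(time, event)`` pair, or an ``(n, 2)`` array.
        """
        X = np.ascontiguousarray(X, dtype=float)
        time, event = check_time_event(y)
        if X.shape[0] != time.size:
            raise ValueError("X and y have different lengths")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        n, n_features = X.shape
        self.n_features_in_ = n_features
        self.kinds_ = self._resolve_kinds(X)
        mtry = self.mtry if self.mtry is not None else max(1, math.floor(math.sqrt(n_features)))
        if not 1 <= mtry <= n_features:
            raise ValueError("mtry must satisfy 1 <= mtry <= n_features")
        self.mtry_ = int(mtry)
        grid = np.unique(time[event == 1])
        if grid.size == 0:
            grid = np.array([time.max()])
        self.event_times_ = grid
        # per-row grid indices shared by node statistics and leaf estimates
        ri_grid = np.searchsorted(grid, time, side="right").astype(np.int64)
        ei_grid = np.where(event == 1, np.searchsorted(grid, time), -1).astype(np.int64)
        splitter = self._make_splitter()
        ss = np.random.SeedSequence(self.random_state)
        self.trees_ = []
        oob = np.zeros((self.n_trees, n), dtype=bool)
        for b, child in enumerate(ss.spawn(self.n_trees)):
            rng = np.random.default_rng(child)
            inbag, oob_b = draw_bootstrap(n, rng)
            oob[b] = oob_b
            self.trees_.append(grow_tree(
                X, time, event, self.kinds_, inbag, splitter,
                mtry=self.mtry_, min_node_size=self.min_node_size,
                min_node_events=self.min_node_events, alpha=self.alpha,
                grid=grid, rng=rng, ri_grid=ri_grid, ei_grid=ei_grid,
            ))
        self.oob_mask_ = oob
        self._fit_X = X
        self._fit_time = time
        self._fit_event = event
        return self

    # -- prediction ---------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "trees_"):
            raise RuntimeError("forest is not fitted")

    def _accumulate(self, X, which, tree_subset=None):
        self._check_fitted()
        X = np.ascontiguousarray(X, dtype=float)
        trees = self.trees_ if tree_subset is None else [self.trees_[b] for b in tree_subset]
        total = np.zeros((X.shape[0], self.event_times_.size))
        for tree in trees:
            leaves = tree.apply(X)
            total += (tree.leaf_chf if which == "chf" else tree.leaf_surv)[leaves]
        return total / len(trees)

    def predict_cumulative_hazard(self, X):
        """Ensemble Nelson–Aalen CHF on the training event-time grid,
        shape ``(n_samples, len(event_times_))``."""
        return self._accumulate(X, "chf")

    def predict_survival(self, X, times=None):
        """Ensemble Kaplan–Meier survival (clipped to [0, 1]).

        With ``times`` given, the step function on ``event_times_`` is
        evaluated there by last-value carry-forward (1 before the first
        event time).
        """
        surv = np.clip(self._accumulate(X, "surv"), 0.0, 1.0)
        if times is None:
            return surv
        idx = np.searchsorted(self.event_times_, np.asarray(times, dtype=float), side="right")
        padded = np.concatenate([np.ones((surv.shape[0], 1)), surv], axis=1)
        return padded[:, idx]

    def predict(self, X):
        """Risk score: ensemble CHF summed over the event-time grid."""
        return self.predict_cumulative_hazard(X).sum(axis=1)

    # -- out-of-bag ---------------------------------------------------

    def _tree_risk_matrix(self, X):
        """Per-tree leaf risk for each row, shape ``(n_trees, n)``."""
        self._check_fitted()
        X = np.ascontiguousarray(X, dtype=float)
        out = np.empty((len(self.trees_), X.shape[0]))
        for b, tree in enumerate(self.trees_):
            out[b] = tree.leaf_risk[tree.apply(X)]
        return out

    def oob_risk(self):
        """OOB ensemble risk of the training subjects.

        Returns ``(risk, valid)``: subjects out-of-bag in no tree carry
        NaN risk and ``valid = False``.
        """
        self._check_fitted()
        risk_mat = self._tree_risk_matrix(self._fit_X)
        counts = self.oob_mask_.sum(axis=0)
        valid = counts > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            risk = np.where(self.oob_mask_, risk_mat, 0.0).sum(axis=0) / counts
        risk[~valid] = np.nan
        return risk, valid

    def oob_predict_cumulative_hazard(self):
        """OOB ensemble CHF for training subjects (NaN rows where a
        subject was in-bag in every tree)."""
        self._check_fitted()
        n = self._fit_X.shape[0]
        total = np.zeros((n, self.event_times_.size))
        counts = self.oob_mask_.sum(axis=0)
        for b, tree in enumerate(self.trees_):
            rows = np.flatnonzero(self.oob_mask_[b])
            if rows.size:
                total[rows] += tree.leaf_chf[tree.apply(self._fit_X[rows])]
        valid = counts > 0
        out = np.full_like(total, np.nan)
        out[valid] = total[valid] / counts[valid, None]
        return out, valid

    # -- persistence --------------------------------------------------

    def save(self, path):
        """Serialize the fitted ensemble (trees + grid) to JSON."""
        self._check_fitted()
        payload = {
            "rule": self._rule,
            "params": self.get_params(),
            "event_times": self.event_times_.tolist(),
            "kinds": self.kinds_.tolist(),
            "trees": [t.to_dict() for t in self.trees_],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            payload = json.load(fh)
        est = _RULE_TO_CLASS[payload["rule"]](**payload["params"])
        est.event_times_ = np.asarray(payload["event_times"], dtype=float)
        est.kinds_ = np.asarray(payload["kinds"], dtype=np.int64)
        est.trees_ = [SurvivalTree.from_dict(d) for d in payload["trees"]]
        est.n_features_in_ = len(est.kinds_)
        return est


class RandomSurvivalForest(SurvivalForestBase):
    """Random survival forest with log-rank splitting: the candidate
    variable and cutpoint maximising |L(X_j, c)| split the node; depth is
    limited by node-size constraints only."""

    _rule = "logrank"


class ConditionalInferenceForest(SurvivalForestBase):
    """Conditional-inference forest: permutation linear-rank association
    tests select the split variable (Bonferroni-adjusted over the drawn
    candidates, alpha-stopping), then a standardized two-sample statistic
    selects the cutpoint."""

    _rule = "conditional"


class MaxstatSurvivalForest(SurvivalForestBase):
    """Survival forest with maximally selected rank statistics: each
    candidate's best cutpoint and multiplicity-adjusted p-value come from
    one scan over log-rank scores; the smallest-p candidate splits the
    node if its Bonferroni-adjusted p-value beats alpha."""

    _rule = "maxstat"


_RULE_TO_CLASS = {
    "logrank": RandomSurvivalForest,
    "conditional": ConditionalInferenceForest,
    "maxstat": MaxstatSurvivalForest,
}
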