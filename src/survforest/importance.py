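"""Out-of-bag permutation variable importance and the top-rank
selection-frequency statistic.

The importance of a covariate is the increase in out-of-bag prediction
error after its column is permuted: baseline error is ``1 - C`` of the
OOB ensemble risk score (Harrell's C), the column is shuffled with a
fixed per-variable sub-seed, OOB predictions are recomputed and
``VIM = permuted error - baseline error``.  A variable used by no split
in any tree cannot change routing, so its VIM is exactly 0 (the
permutation is skipped).

Across simulation replicates the headline statistic is the selection
frequency: the fraction of replicates in which both truly prognostic
covariates occupy VIM ranks 1 and 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._survival import check_time_event
from .metrics import harrell_c


def _vim_ranks(vim):
    """Ranks 1..M, descending importance, ties broken by variable index."""
    order = np.lexsort((np.arange(vim.size), -vim))
    ranks = np.empty(vim.size, dtype=np.int64)
    ranks[order] = np.arange(1, vim.size + 1)
    return ranks


def permutation_importance(forest, X=None, y=None, n_perm=1, random_state=0):
    """Permutation VIM table for a fitted forest.

    ``X``/``y`` default to the forest's training data (the usual OOB
    convention).  Only trees whose split set contains the permuted
    variable are re-routed, and only at their OOB rows; other trees'
    contributions to the ensemble risk are unchanged.

    Returns a DataFrame with columns ``variable``, ``vim``, ``rank``.
    """
    if X is None:
        X, time, event = forest._fit_X, forest._fit_time, forest._fit_event
    else:
        X = np.ascontiguousarray(X, dtype=float)
        time, event = check_time_event(y)
    n = X.shape[0]
    n_features = forest.n_features_in_
    oob = forest.oob_mask_
    counts = oob.sum(axis=0)
    valid = counts > 0
    risk_mat = forest._tree_risk_matrix(X)
    base_risk = np.where(oob, risk_mat, 0.0).sum(axis=0)
    base_err = 1.0 - harrell_c(
        (base_risk[valid] / counts[valid]), time[valid], event[valid]
    )
    trees_using = {}
    for b, tree in enumerate(forest.trees_):
        for f in tree.split_features:
            trees_using.setdefault(int(f), []).append(b)
    vim = np.zeros(n_features)
    for v, tree_ids in trees_using.items():
        rng = np.random.default_rng(np.random.SeedSequence([int(random_state), v]))
        acc = 0.0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Xp = X.copy()
            Xp[:, v] = X[perm, v]
            perm_risk = base_risk.copy()
            for b in tree_ids:
                rows = np.flatnonzero(oob[b])
                if rows.size == 0:
                    continue
                tree = forest.trees_[b]
                new_r = tree.leaf_risk[tree.apply(Xp[rows])]
                perm_risk[rows] += new_r - risk_mat[b, rows]
            err = 1.0 - harrell_c(
                perm_risk[valid] / counts[valid], time[valid], event[valid]
            )
            acc += err - base_err
        vim[v] = acc / n_perm
    return pd.DataFrame({
        "variable": np.arange(n_features),
        "vim": vim,
        "rank": _vim_ranks(vim),
    })


def selection_frequency(vim_tables, causal_ids):
    """Fraction of replicates where both causal variables rank in the
    top 2 by VIM.

    ``vim_tables`` is an iterable of VIM DataFrames (one per replicate)
    or of rank arrays indexed by variable.
    """
    causal_ids = tuple(int(c) for c in causal_ids)
    if len(causal_ids) != 2:
        raise ValueError("exactly two causal variables are expected")
    hits, total = 0, 0
    for tab in vim_tables:
        if isinstance(tab, pd.DataFrame):
            ranks = tab.set_index("variable")["rank"]
            r = [int(ranks.loc[c]) for c in causal_ids]
        else:
            arr = np.asarray(tab)
            r = [int(arr[c]) for c in causal_ids]
        hits += int(max(r) <= 2)
        total += 1
    if total == 0:
        raise ValueError("no replicates supplied")
    return hits / total
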