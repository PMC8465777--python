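"""Log-rank split rule against brute-force and external oracles."""

import itertools

import numpy as np
import pytest

from survforest.split_logrank import LogrankSplitter, logrank_statistic


def brute_force_best(X, kinds, time, event, candidates):
    """Exhaustive (variable x cutpoint / level-subset) search, computed
    independently of the prefix-scan implementation."""
    best = None
    for j in candidates:
        x = X[:, j]
        k = int(kinds[j])
        if k >= 2:
            levels = np.arange(1, k + 1)
            memberships = []
            for r in range(1, k):
                for sub in itertools.combinations(levels, r):
                    memberships.append((set(sub), np.isin(x, sub)))
        else:
            vals = np.unique(x)
            memberships = [
                (0.5 * (lo + hi), x <= 0.5 * (lo + hi))
                for lo, hi in zip(vals[:-1], vals[1:])
            ]
        for where, left in memberships:
            if left.all() or not left.any():
                continue
            L = logrank_statistic(time, event, left)
            if np.isfinite(L) and (best is None or abs(L) > abs(best[0]) + 1e-12):
                best = (L, j, where)
    return best


def _find(splitter, X, kinds, time, event, candidates):
    cand = np.sort(np.asarray(candidates))
    return splitter.find_split(X[:, cand], kinds[cand], time, event, cand)


def test_statistic_symmetry_and_antisymmetry(rng):
    # identical (time,event) multisets in both children -> L = 0
    t = np.array([1.0, 2, 3, 1, 2, 3])
    e = np.array([1, 0, 1, 1, 0, 1])
    left = np.array([True, True, True, False, False, False])
    assert logrank_statistic(t, e, left) == pytest.approx(0.0, abs=1e-12)
    # swapping children flips the sign
    t = rng.exponential(1, 10)
    e = rng.integers(0, 2, 10)
    e[0] = 1
    left = np.zeros(10, bool)
    left[:4] = True
    assert logrank_statistic(t, e, left) == pytest.approx(
        -logrank_statistic(t, e, ~left)
    )


def test_statistic_matches_external_logrank(rng):
    """L^2 equals the chi-square of the standard two-sample log-rank test."""
    from sksurv.compare import compare_survival
    from sksurv.util import Surv

    for _ in range(10):
        n = int(rng.integers(8, 40))
        t = rng.exponential(1, n)
        e = rng.integers(0, 2, n)
        left = rng.random(n) < 0.5
        if left.all() or not left.any() or e.sum() == 0:
            continue
        L = logrank_statistic(t, e, left)
        if not np.isfinite(L):
            continue
        chi2, _ = compare_survival(Surv.from_arrays(e.astype(bool), t), left.astype(int))
        assert L**2 == pytest.approx(chi2, rel=1e-10)


@pytest.mark.parametrize("n", [10, 30])
def test_best_split_equals_brute_force(rng, n):
    splitter = LogrankSplitter()
    for _ in range(8):
        X = np.column_stack([
            rng.normal(size=n),
            rng.integers(0, 3, n).astype(float),
            rng.normal(size=n),
        ])
        kinds = np.zeros(3, dtype=np.int64)
        time = rng.exponential(1, n)
        event = rng.integers(0, 2, n)
        event[:3] = 1
        dec = _find(splitter, X, kinds, time, event, [0, 1, 2])
        oracle = brute_force_best(X, kinds, time, event, [0, 1, 2])
        assert (dec is None) == (oracle is None)
        if dec is not None:
            assert abs(dec.statistic) == pytest.approx(abs(oracle[0]), rel=1e-10)
            assert dec.feature == oracle[1]


def test_factor_split_equals_brute_force(rng):
    n = 40
    splitter = LogrankSplitter()
    kinds = np.array([4, 0], dtype=np.int64)
    for _ in range(5):
        X = np.column_stack([
            rng.integers(1, 5, n).astype(float),
            rng.normal(size=n),
        ])
        time = rng.exponential(1, n)
        event = rng.integers(0, 2, n)
        event[:3] = 1
        dec = _find(splitter, X, kinds, time, event, [0, 1])
        oracle = brute_force_best(X, kinds, time, event, [0, 1])
        assert abs(dec.statistic) == pytest.approx(abs(oracle[0]), rel=1e-10)
        assert dec.feature == oracle[1]
        if dec.feature == 0:
            left_levels = {lev for lev in range(1, 5) if (dec.level_mask >> (lev - 1)) & 1}
            assert left_levels in (oracle[2], set(range(1, 5)) - oracle[2])


def test_monotone_transform_invariance(rng):
    n = 25
    splitter = LogrankSplitter()
    x = rng.normal(size=n)
    time = rng.exponential(1, n)
    event = np.ones(n, dtype=int)
    kinds = np.zeros(1, dtype=np.int64)
    d1 = _find(splitter, x[:, None], kinds, time, event, [0])
    d2 = _find(splitter, np.exp(x)[:, None], kinds, time, event, [0])
    assert d1.statistic == pytest.approx(d2.statistic, rel=1e-10)
    assert (x <= d1.threshold).sum() == (np.exp(x) <= d2.threshold).sum()


def test_no_events_or_constant_candidates_yield_no_split(rng):
    splitter = LogrankSplitter()
    n = 12
    X = np.column_stack([np.ones(n), np.full(n, 3.0)])
    kinds = np.zeros(2, dtype=np.int64)
    t = rng.exponential(1, n)
    assert _find(splitter, X, kinds, t, np.ones(n, int), [0, 1]) is None
    X2 = rng.normal(size=(n, 2))
    assert _find(splitter, X2, kinds, t, np.zeros(n, int), [0, 1]) is None


def test_perfect_separator_is_selected(rng):
    # variable 0 separates early deaths from late deaths; variable 1 is noise
    n = 12
    time = np.concatenate([np.arange(1, 7) * 0.1, np.arange(1, 7) * 10.0])
    event = np.ones(n, dtype=int)
    X = np.column_stack([
        np.concatenate([np.zeros(6), np.ones(6)]),
        rng.normal(size=n),
    ])
    kinds = np.zeros(2, dtype=np.int64)
    dec = _find(LogrankSplitter(), X, kinds, time, event, [0, 1])
    assert dec.feature == 0
    assert 0.0 < dec.threshold < 1.0


def test_single_binary_candidate_forced_choice():
    t = np.array([1.0, 2, 3, 4, 5, 6])
    e = np.ones(6, int)
    x = np.array([0.0, 1, 0, 1, 0, 1])
    dec = _find(LogrankSplitter(), x[:, None], np.zeros(1, np.int64), t, e, [0])
    assert dec.threshold == pytest.approx(0.5)
    assert dec.statistic == pytest.approx(logrank_statistic(t, e, x <= 0.5), rel=1e-10)
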