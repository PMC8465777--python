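"""Forest engine: bootstrap, growth constraints, leaf estimates, ensemble
prediction, OOB bookkeeping, determinism and persistence."""

import numpy as np
import pytest

from survforest import (
    ConditionalInferenceForest,
    MaxstatSurvivalForest,
    RandomSurvivalForest,
    SurvivalForestBase,
)
from survforest.tree import draw_bootstrap

ALL_FORESTS = [RandomSurvivalForest, ConditionalInferenceForest, MaxstatSurvivalForest]


def test_bootstrap_oob_fraction(rng):
    # n=1: the only subject is always drawn
    inbag, oob = draw_bootstrap(1, rng)
    assert inbag.tolist() == [0] and not oob.any()
    # exact expectation (1 - 1/n)^n at n=4
    assert (1 - 1 / 4) ** 4 == pytest.approx(0.3164, abs=5e-5)
    # mean OOB fraction at n=1000 approaches e^-1 (36.8%)
    fracs = [draw_bootstrap(1000, rng)[1].mean() for _ in range(2000)]
    assert np.mean(fracs) == pytest.approx(0.368, abs=0.003)


@pytest.mark.parametrize("cls", ALL_FORESTS)
def test_fit_predict_shapes_and_monotonicity(cls, model_c_data):
    train, test = model_c_data
    f = cls(n_trees=25, random_state=0).fit(train.X, train.y)
    chf = f.predict_cumulative_hazard(test.X)
    surv = f.predict_survival(test.X)
    assert chf.shape == (len(test), f.event_times_.size)
    assert (np.diff(chf, axis=1) >= -1e-10).all()
    assert (np.diff(surv, axis=1) <= 1e-10).all()
    assert surv.min() >= 0 and surv.max() <= 1
    # survival evaluated before the first event time is 1
    early = f.predict_survival(test.X, times=[f.event_times_[0] / 2])
    assert np.allclose(early, 1.0)
    risk = f.predict(test.X)
    assert np.allclose(risk, chf.sum(axis=1))


@pytest.mark.parametrize("cls", ALL_FORESTS)
def test_determinism(cls, model_c_data):
    train, test = model_c_data
    f1 = cls(n_trees=10, random_state=42).fit(train.X, train.y)
    f2 = cls(n_trees=10, random_state=42).fit(train.X, train.y)
    assert np.array_equal(f1.predict(test.X), f2.predict(test.X))
    assert np.array_equal(f1.oob_mask_, f2.oob_mask_)
    f3 = cls(n_trees=10, random_state=43).fit(train.X, train.y)
    assert not np.array_equal(f1.predict(test.X), f3.predict(test.X))


def test_routing_partitions_sample(model_c_data):
    train, _ = model_c_data
    f = RandomSurvivalForest(n_trees=5, random_state=1).fit(train.X, train.y)
    for tree in f.trees_:
        leaves = tree.apply(train.X)
        assert (leaves >= 0).all() and (leaves < tree.leaf_chf.shape[0]).all()
        # children partition the parent exactly: every member reaches one leaf
        assert leaves.size == len(train)


def test_two_group_ordering():
    # hugely different hazards: ensemble survival must order the groups
    rng = np.random.default_rng(5)
    n = 200
    g = np.repeat([0.0, 1.0], n // 2)
    t = np.where(g == 0, 0.05, 5.0) * rng.exponential(1, n)
    X = np.column_stack([g, rng.normal(size=n)])
    f = RandomSurvivalForest(n_trees=200, random_state=0).fit(X, (t, np.ones(n, int)))
    risk = f.predict(np.array([[0.0, 0.0], [1.0, 0.0]]))
    assert risk[0] > risk[1]
    surv = f.predict_survival(np.array([[0.0, 0.0], [1.0, 0.0]]))
    mid = f.event_times_.size // 2
    assert surv[0, mid] < surv[1, mid]


def test_single_tree_forest_oob(model_c_data):
    train, _ = model_c_data
    f = RandomSurvivalForest(n_trees=1, random_state=0).fit(train.X, train.y)
    risk, valid = f.oob_risk()
    inbag_only = ~f.oob_mask_[0]
    assert (~valid == inbag_only).all()
    assert np.isnan(risk[~valid]).all()


def test_oob_average_uses_only_oob_trees(model_c_data):
    train, _ = model_c_data
    f = RandomSurvivalForest(n_trees=3, random_state=0).fit(train.X, train.y)
    risk_mat = f._tree_risk_matrix(train.X)
    risk, valid = f.oob_risk()
    i = int(np.flatnonzero(valid)[0])
    trees = np.flatnonzero(f.oob_mask_[:, i])
    assert risk[i] == pytest.approx(risk_mat[trees, i].mean())
    # a subject OOB in every tree gets the full-ensemble prediction
    all_oob = np.flatnonzero(f.oob_mask_.all(axis=0))
    if all_oob.size:
        j = int(all_oob[0])
        assert risk[j] == pytest.approx(risk_mat[:, j].mean())


def test_ensemble_is_tree_average(model_c_data):
    train, test = model_c_data
    f = MaxstatSurvivalForest(n_trees=4, random_state=3).fit(train.X, train.y)
    manual = np.mean(
        [t.leaf_chf[t.apply(test.X)] for t in f.trees_], axis=0
    )
    assert np.allclose(f.predict_cumulative_hazard(test.X), manual)


def test_all_censored_training_yields_null_hazard():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 3))
    t = rng.exponential(1, 30)
    f = RandomSurvivalForest(n_trees=5, random_state=0).fit(X, (t, np.zeros(30, int)))
    assert np.allclose(f.predict_cumulative_hazard(X), 0.0)
    assert np.allclose(f.predict_survival(X), 1.0)


def test_node_size_constraints_limit_leaves(model_c_data):
    train, _ = model_c_data
    small = RandomSurvivalForest(n_trees=5, min_node_size=2, min_node_events=1,
                                 random_state=0).fit(train.X, train.y)
    big = RandomSurvivalForest(n_trees=5, min_node_size=40, min_node_events=20,
                               random_state=0).fit(train.X, train.y)
    n_leaves = lambda f: np.mean([t.leaf_chf.shape[0] for t in f.trees_])
    assert n_leaves(big) < n_leaves(small)


def test_unseen_factor_level_routes_to_majority_child():
    rng = np.random.default_rng(2)
    n = 120
    lev = rng.integers(1, 4, n).astype(float)  # levels 1..3 of a 4-level factor
    t = np.where(lev == 1, 0.05, 5.0) * rng.exponential(1, n)
    X = lev[:, None]
    f = RandomSurvivalForest(n_trees=10, categorical_features={0: 4},
                             random_state=0).fit(X, (t, np.ones(n, int)))
    # level 4 never occurs in training; prediction must not fail
    risk = f.predict(np.array([[4.0]]))
    assert np.isfinite(risk).all()


def test_validation_errors(model_c_data):
    train, _ = model_c_data
    with pytest.raises(ValueError):
        RandomSurvivalForest(alpha=1.5).fit(train.X, train.y)
    with pytest.raises(ValueError):
        RandomSurvivalForest(mtry=99).fit(train.X, train.y)
    with pytest.raises(ValueError):
        RandomSurvivalForest().fit(train.X, (np.zeros(len(train)), train.event))


def test_sklearn_params_round_trip():
    f = MaxstatSurvivalForest(n_trees=7, minprop=0.2)
    params = f.get_params()
    assert params["n_trees"] == 7 and params["minprop"] == 0.2
    f.set_params(n_trees=9)
    assert f.n_trees == 9


def test_json_save_load_round_trip(tmp_path, model_c_data):
    train, test = model_c_data
    f = RandomSurvivalForest(n_trees=5, random_state=0).fit(train.X, train.y)
    path = tmp_path / "forest.json"
    f.save(path)
    g = SurvivalForestBase.load(path)
    assert np.allclose(g.predict(test.X), f.predict(test.X))
    assert np.allclose(g.predict_survival(test.X), f.predict_survival(test.X))
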