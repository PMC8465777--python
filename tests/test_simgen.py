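"""Generator checks: linear predictors, covariate laws, survival-time
distribution and censoring calibration."""

import numpy as np
import pytest

from survforest.simgen import (
    GeneratorSpec,
    SurvivalDataset,
    calibrate_censoring,
    generate_covariates,
    generate_survival,
    linear_predictor,
    make_replicate,
)


@pytest.mark.parametrize(
    "model_id, row, expected",
    [
        # x1..x10 layouts; indicator terms evaluate to {0, 1}
        ("A1", [1, 0, 0, 0, 2, 1, 1, 1, 1, 1], 2.5),
        ("A1", [0.2, 0, 0, 0, 1, 2, 1, 1, 1, 1], 0.3),
        ("A2", [0.4, 0, 0, 0, 1, 1, 3, 1, 1, 1], 1.6),
        ("A3", [0.0, 0, 0, 0, 1, 1, 1, 1, 5, 1], 1.0),
        ("B1", [0.4, 0, 0, 0, 2, 1, 1, 1, 1, 1], 0.0),
        ("B1", [0.6, 0, 0, 0, 2, 1, 1, 1, 1, 1], 1.0),
        ("B3", [0.9, 0, 0, 0, 1, 1, 1, 1, 4, 1], 0.0),
        ("C", [1.0, 2.0, 0, 0, 0, 0, 0, 0, 0, 0], 4.0),
    ],
)
def test_linear_predictor_examples(model_id, row, expected):
    eta = linear_predictor(model_id, np.asarray([row], dtype=float))
    assert eta[0] == pytest.approx(expected)


def test_linear_predictor_d_models():
    X = np.array([[1.0, 1.0, 9.0, -3.0]])
    for mid in ("D1", "D2"):
        assert linear_predictor(mid, X)[0] == pytest.approx(5.0)
    with pytest.raises(ValueError):
        linear_predictor("Z9", X)


def test_covariate_laws(rng):
    spec = GeneratorSpec("A1", n_train=80_000, target_censoring=0.0)
    X, kinds, causal = generate_covariates(spec, rng)
    assert causal == (0, 4)
    assert list(kinds) == [0, 0, 0, 0, 2, 2, 4, 4, 8, 8]
    # eight-level discrete uniform: each level frequency 1/8
    freq = np.bincount(X[:, 8].astype(int), minlength=9)[1:] / len(X)
    assert np.allclose(freq, 0.125, atol=0.005)
    assert abs(X[:, 0].mean() - 0.5) < 0.01 and abs(X[:, 2].mean()) < 0.02


def test_equicorrelated_mvn(rng):
    spec = GeneratorSpec("C", n_train=80_000, target_censoring=0.0, rho=0.8)
    X, kinds, causal = generate_covariates(spec, rng)
    assert causal == (0, 1) and (kinds == 0).all()
    corr = np.corrcoef(X, rowvar=False)
    off = corr[~np.eye(10, dtype=bool)]
    assert np.allclose(off, 0.8, atol=0.01)

    spec0 = GeneratorSpec("C", n_train=80_000, target_censoring=0.0, rho=0.0)
    X0, _, _ = generate_covariates(spec0, rng)
    corr0 = np.corrcoef(X0, rowvar=False)
    assert np.abs(corr0[~np.eye(10, dtype=bool)]).max() < 0.03


def test_survival_time_distribution(rng):
    # T | eta=0 is exponential with mean e^0.5 and median e^0.5 log 2
    T = generate_survival(np.zeros(500_000), rng)
    assert (T > 0).all()
    assert T.mean() == pytest.approx(np.exp(0.5), abs=0.01)
    assert np.median(T) == pytest.approx(np.exp(0.5) * np.log(2), abs=0.01)


def test_conditional_mean_of_survival_time(rng):
    # regression of T on exp(0.5 + eta) through the origin has slope 1
    eta = rng.normal(0, 1, 200_000)
    T = generate_survival(eta, rng)
    m = np.exp(0.5 + eta)
    slope = np.sum(T * m) / np.sum(m * m)
    assert slope == pytest.approx(1.0, abs=0.02)


def test_censoring_calibration_no_censoring():
    spec = GeneratorSpec("C", n_train=50, target_censoring=0.0, rho=0.0)
    assert calibrate_censoring(spec) == 0.0
    train, test = make_replicate(spec, np.random.default_rng(0))
    assert train.event.all() and test.event.all()


@pytest.mark.parametrize("target", [0.25, 0.5, 0.75])
def test_censoring_calibration_hits_target(target, rng):
    spec = GeneratorSpec("C", n_train=80_000, target_censoring=target, rho=0.0)
    train, test = make_replicate(spec, rng)
    realized = 1.0 - np.concatenate([train.event, test.event]).mean()
    assert realized == pytest.approx(target, abs=0.01)


def test_conditional_censoring_probability_identity():
    # with lambda = mu the conditional censoring probability is exactly 1/2,
    # so a symmetric-eta model calibrated to 0.5 must return lambda near
    # the harmonic balance point; check the identity on the realized data
    spec = GeneratorSpec("D2", n_train=40_000, target_censoring=0.5, n_covariates=2)
    train, test = make_replicate(spec, np.random.default_rng(3))
    realized = 1.0 - np.concatenate([train.event, test.event]).mean()
    assert realized == pytest.approx(0.5, abs=0.015)


def test_make_replicate_shapes_and_determinism():
    spec = GeneratorSpec("C", n_train=200, target_censoring=0.25, rho=0.0, seed=42)
    tr1, te1 = make_replicate(spec)
    tr2, te2 = make_replicate(spec)
    assert len(tr1) == 200 and len(te1) == 50
    assert np.array_equal(tr1.time, tr2.time) and np.array_equal(tr1.X, tr2.X)
    assert np.array_equal(te1.event, te2.event)
    assert (tr1.time > 0).all()
    assert tr1.causal_ids == (0, 1)


def test_spec_validation():
    with pytest.raises(ValueError):
        GeneratorSpec("A1", n_train=100, rho=0.5)  # rho is model-C only
    with pytest.raises(ValueError):
        GeneratorSpec("D1", n_train=100)  # M required
    with pytest.raises(ValueError):
        GeneratorSpec("C", n_train=100, target_censoring=1.0)
    with pytest.raises(ValueError):
        GeneratorSpec("A1", n_train=100, n_covariates=5)


def test_csv_round_trip(tmp_path):
    spec = GeneratorSpec("A1", n_train=400, target_censoring=0.25, seed=1)
    train, _ = make_replicate(spec)
    path = tmp_path / "train.csv"
    train.to_csv(path)
    back = SurvivalDataset.from_csv(path, categorical=[f"x{j}" for j in (5, 6, 7, 8, 9, 10)])
    assert np.allclose(back.time, train.time)
    assert np.array_equal(back.event, train.event)
    assert np.allclose(back.X, train.X)
    assert np.array_equal(back.kinds, train.kinds)
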