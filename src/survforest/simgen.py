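"""Synthetic right-censored survival data: nine benchmark generating models.

Every model draws survival times by inverse transform from an
exponential model,

    T = -log(U) * exp(0.5 + beta' X),   U ~ U(0, 1) open interval,

so ``T | X`` is exponential with mean ``exp(0.5 + eta)``, and censoring
times from an exponential distribution whose rate is calibrated so that
the marginal censoring probability ``E_X[ lambda / (lambda + mu(X)) ]``
(``mu(X) = exp(-(0.5 + eta))``) hits a target rate.  Exactly two
covariates carry signal in every model; the rest are noise.

Model catalogue (``eta = beta' X`` per row):

====== ============================== =========================================
model  linear predictor               covariates
====== ============================== =========================================
A1     1.5 x1 + I(x5 = 2)             x1-x2 ~ U(0,1), x3-x4 ~ N(0,1),
A2     1.5 x1 + I(x7 >= 3)            x5-x6 ~ DU(1,2), x7-x8 ~ DU(1,4),
A3     1.5 x1 + I(x9 >= 5)            x9-x10 ~ DU(1,8); DU levels unordered
B1     I(x1 > 0.5) * I(x5 = 2)        same frame as A (interaction form)
B2     I(x1 > 0.5) * I(x7 >= 3)
B3     I(x1 > 0.5) * I(x9 >= 5)
C      x1 + 1.5 x2                    x1-x10 ~ MVN(0, Sigma(rho)), equicorrelated
D1     2 x1 + 3 x2                    x1-xM iid N(0,1)
D2     2 x1 + 3 x2                    x1-xM iid DU(1,2) (ordered binary)
====== ============================== =========================================

The indicator cutoffs of models A/B are placed so that half the subjects
score 1.  Models A/B always have M = 10 covariates; C has 10; D has a
configurable M.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

MODEL_IDS = ("A1", "A2", "A3", "B1", "B2", "B3", "C", "D1", "D2")

#: seed of the fixed covariate sample used to calibrate censoring rates
_CALIBRATION_SEED = 20210925
_CALIBRATION_N = 100_000

_CAUSAL = {
    "A1": (0, 4), "A2": (0, 6), "A3": (0, 8),
    "B1": (0, 4), "B2": (0, 6), "B3": (0, 8),
    "C": (0, 1), "D1": (0, 1), "D2": (0, 1),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Fully determines one simulation condition.

    ``rho`` applies to model C only (equicorrelation), ``n_covariates``
    to models D1/D2 only; supplying either elsewhere is a configuration
    error.  ``target_censoring`` is the marginal probability that a
    subject is censored.
    """

    model_id: str
    n_train: int
    target_censoring: float = 0.0
    test_fraction: float = 0.2
    rho: Optional[float] = None
    n_covariates: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.n_train < 1:
            raise ValueError("n_train must be positive")
        if not 0.0 <= self.target_censoring < 1.0:
            raise ValueError("target_censoring must lie in [0, 1)")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.model_id == "C":
            rho = 0.0 if self.rho is None else self.rho
            if not 0.0 <= rho < 1.0:
                raise ValueError("rho must lie in [0, 1)")
        elif self.rho is not None:
            raise ValueError("rho applies to model C only")
        if self.model_id in ("D1", "D2"):
            if self.n_covariates is None or self.n_covariates < 2:
                raise ValueError("models D1/D2 need n_covariates >= 2")
        elif self.n_covariates is not None:
            raise ValueError("n_covariates applies to models D1/D2 only")

    @property
    def n_features(self) -> int:
        return self.n_covariates if self.model_id in ("D1", "D2") else 10


@dataclass
class SurvivalDataset:
    """Observed right-censored data with covariate-kind metadata.

    ``kinds[j] = 0`` marks a numeric/ordered column, ``k >= 2`` an
    unordered factor with levels ``1..k``.  ``causal_ids`` lists the two
    outcome-associated columns for synthetic data (``None`` for real
    data).
    """

    time: np.ndarray
    event: np.ndarray
    X: np.ndarray
    kinds: np.ndarray
    causal_ids: Optional[tuple] = None
    feature_names: Optional[list] = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        self.kinds = np.asarray(self.kinds, dtype=np.int64)
        if np.any(self.time <= 0):
            raise ValueError("survival times must be strictly positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")

    def __len__(self):
        return self.time.size

    @property
    def y(self):
        """Response as a ``(time, event)`` pair accepted by the forests."""
        return (self.time, self.event)

    def categorical_features(self):
        """Dict {column: level count} for the forests' factor handling."""
        return {int(j): int(k) for j, k in enumerate(self.kinds) if k >= 2}

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or [f"x{j + 1}" for j in range(self.X.shape[1])]
        df = pd.DataFrame(self.X, columns=names)
        df.insert(0, "status", self.event)
        df.insert(0, "time", self.time)
        return df

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, categorical=()):
        """Read ``time,status,x...`` CSV; ``categorical`` names columns
        to recode as unordered factors (labels become codes ``1..k``)."""
        df = pd.read_csv(path)
        return cls.from_frame(df, categorical=categorical)

    @classmethod
    def from_frame(cls, df, categorical=()):
        missing = {"time", "status"} - set(df.columns)
        if missing:
            raise ValueError(f"CSV lacks required columns: {sorted(missing)}")
        features = [c for c in df.columns if c not in ("time", "status")]
        X = np.empty((len(df), len(features)))
        kinds = np.zeros(len(features), dtype=np.int64)
        for j, name in enumerate(features):
            if name in categorical:
                codes, _ = pd.factorize(df[name], sort=True)
                X[:, j] = codes + 1.0
                kinds[j] = codes.max() + 1
            else:
                X[:, j] = df[name].to_numpy(dtype=float)
        return cls(df["time"].to_numpy(dtype=float),
                   df["status"].to_numpy(dtype=int),
                   X, kinds, causal_ids=None, feature_names=features)


def linear_predictor(model_id, X):
    """beta' X per row for the given model (Table of models above)."""
    X = np.asarray(X, dtype=float)
    if model_id == "A1":
        return 1.5 * X[:, 0] + (X[:, 4] == 2)
    if model_id == "A2":
        return 1.5 * X[:, 0] + (X[:, 6] >= 3)
    if model_id == "A3":
        return 1.5 * X[:, 0] + (X[:, 8] >= 5)
    if model_id == "B1":
        return 1.0 * (X[:, 0] > 0.5) * (X[:, 4] == 2)
    if model_id == "B2":
        return 1.0 * (X[:, 0] > 0.5) * (X[:, 6] >= 3)
    if model_id == "B3":
        return 1.0 * (X[:, 0] > 0.5) * (X[:, 8] >= 5)
    if model_id == "C":
        return X[:, 0] + 1.5 * X[:, 1]
    if model_id in ("D1", "D2"):
        return 2.0 * X[:, 0] + 3.0 * X[:, 1]
    raise ValueError(f"unknown model_id {model_id!r}")


def generate_covariates(spec, rng):
    """Draw the covariate matrix for one replicate.

    Returns ``(X, kinds, causal_ids)``; factor columns hold equiprobable
    integer codes ``1..k``.
    """
    n = _total_n(spec)
    return _draw_covariates(spec.model_id, n,
                            rho=spec.rho, n_covariates=spec.n_covariates, rng=rng)


def _draw_covariates(model_id, n, *, rho=None, n_covariates=None, rng):
    causal = _CAUSAL[model_id]
    if model_id in ("A1", "A2", "A3", "B1", "B2", "B3"):
        X = np.empty((n, 10))
        X[:, 0:2] = rng.random((n, 2))
        X[:, 2:4] = rng.standard_normal((n, 2))
        X[:, 4:6] = rng.integers(1, 3, size=(n, 2))
        X[:, 6:8] = rng.integers(1, 5, size=(n, 2))
        X[:, 8:10] = rng.integers(1, 9, size=(n, 2))
        kinds = np.array([0, 0, 0, 0, 2, 2, 4, 4, 8, 8], dtype=np.int64)
    elif model_id == "C":
        r = 0.0 if rho is None else float(rho)
        cov = np.full((10, 10), r)
        np.fill_diagonal(cov, 1.0)
        chol = np.linalg.cholesky(cov)
        X = rng.standard_normal((n, 10)) @ chol.T
        kinds = np.zeros(10, dtype=np.int64)
    elif model_id == "D1":
        X = rng.standard_normal((n, n_covariates))
        kinds = np.zeros(n_covariates, dtype=np.int64)
    elif model_id == "D2":
        # ordered binary: codes 1/2, split semantics identical either way
        X = rng.integers(1, 3, size=(n, n_covariates)).astype(float)
        kinds = np.zeros(n_covariates, dtype=np.int64)
    else:
        raise ValueError(f"unknown model_id {model_id!r}")
    return X, kinds, causal


def generate_survival(eta, rng):
    """T = -log(U) exp(0.5 + eta) with U resampled away from {0, 1} so
    that survival times are strictly positive and finite."""
    eta = np.asarray(eta, dtype=float)
    u = rng.random(eta.size)
    bad = u <= 0.0
    while bad.any():
        u[bad] = rng.random(int(bad.sum()))
        bad = u <= 0.0
    return -np.log(u) * np.exp(0.5 + eta)


def _sample_eta(model_id, rho, n_covariates, n, rng):
    """Linear predictors of a fresh covariate sample (only the causal
    columns matter, but the full design keeps the code uniform)."""
    X, _, _ = _draw_covariates(model_id, n, rho=rho, n_covariates=2 if model_id in ("D1", "D2") else None, rng=rng)
    return linear_predictor(model_id, X)


@lru_cache(maxsize=None)
def _censoring_rate_cached(model_id, rho_key, target):
    rng = np.random.default_rng(_CALIBRATION_SEED)
    rho = None if rho_key is None else rho_key
    eta = _sample_eta(model_id, rho, None, _CALIBRATION_N, rng)
    mu = np.exp(-(0.5 + eta))

    def frac_censored(log_lam):
        lam = np.exp(log_lam)
        return float(np.mean(lam / (lam + mu))) - target

    log_lam = brentq(frac_censored, -30.0, 30.0, xtol=1e-10)
    return float(np.exp(log_lam))


def calibrate_censoring(spec, target_rate=None):
    """Exponential censoring rate hitting the marginal target.

    Solves ``E_X[lambda / (lambda + mu(X))] = target`` by monotone root
    finding on ``log lambda`` over a fixed large Monte-Carlo covariate
    sample (the solution is cached per model/rho/target).  A target of 0
    returns 0.0, meaning "no censoring".
    """
    target = spec.target_censoring if target_rate is None else target_rate
    if not 0.0 <= target < 1.0:
        raise ValueError("target censoring rate must lie in [0, 1)")
    if target == 0.0:
        return 0.0
    rho_key = None
    if spec.model_id == "C":
        rho_key = round(0.0 if spec.rho is None else float(spec.rho), 10)
    return _censoring_rate_cached(spec.model_id, rho_key, round(float(target), 10))


def _total_n(spec):
    return int(round(spec.n_train / (1.0 - spec.test_fraction)))


def make_replicate(spec, rng=None):
    """Generate one (train, test) replicate.

    Draws ``n_train / (1 - test_fraction)`` subjects, applies censoring
    (observed time ``min(T, C)``, event ``I(T <= C)``) and splits
    uniformly at random so the training set has exactly ``n_train``
    rows.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = _total_n(spec)
    X, kinds, causal = generate_covariates(spec, rng)
    eta = linear_predictor(spec.model_id, X)
    T = generate_survival(eta, rng)
    lam = calibrate_censoring(spec)
    if lam == 0.0:
        time, event = T, np.ones(n, dtype=int)
    else:
        C = rng.exponential(1.0 / lam, size=n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[: spec.n_train])
    test_idx = np.sort(perm[spec.n_train:])
    make = lambda idx: SurvivalDataset(time[idx], event[idx], X[idx], kinds, causal)
    return make(train_idx), make(test_idx)
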