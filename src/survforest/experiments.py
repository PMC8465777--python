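"""Monte-Carlo experiment driver.

One *cell* of the benchmark grid is a :class:`~survforest.simgen.GeneratorSpec`
(model, training size, censoring rate, rho or M).  For every replicate
the driver generates fresh data, fits each requested forest, computes
permutation VIM on the training set, and the IPCW integrated Brier score
and c-index on the held-out test set.  Replicate seeds are derived from
``(master seed, cell, replicate index)`` so any cell can be re-run
independently and the whole table is bit-reproducible.
"""

from __future__ import annotations

import logging
import zlib

import numpy as np
import pandas as pd

from .forest import (
    ConditionalInferenceForest,
    MaxstatSurvivalForest,
    RandomSurvivalForest,
)
from .importance import permutation_importance, selection_frequency
from .metrics import evaluate_predictions
from .simgen import GeneratorSpec, SurvivalDataset, make_replicate

logger = logging.getLogger("survforest")

METHODS = {
    "RSF": RandomSurvivalForest,
    "CIF": ConditionalInferenceForest,
    "MSR-RF": MaxstatSurvivalForest,
}

_CELL_KEYS = ["model_id", "n_train", "censoring", "rho", "M", "method"]


def cell_code(spec: GeneratorSpec) -> int:
    """Stable integer identifying a grid cell (independent of PYTHONHASHSEED)."""
    key = f"{spec.model_id}|{spec.n_train}|{spec.target_censoring}|{spec.rho}|{spec.n_covariates}"
    return zlib.crc32(key.encode())


def replicate_rng(master_seed, spec, rep):
    """Seed sequence for one replicate of one cell."""
    return np.random.SeedSequence([int(master_seed), cell_code(spec), int(rep)])


def _record_base(spec, method, rep):
    return {
        "model_id": spec.model_id,
        "n_train": spec.n_train,
        "censoring": spec.target_censoring,
        "rho": spec.rho,
        "M": spec.n_features,
        "method": method,
        "rep": rep,
    }


def run_cell(spec, methods=("RSF", "CIF", "MSR-RF"), reps=100, master_seed=0,
             n_trees=200, mtry=None, n_perm=1, evaluate_test=True):
    """Run one grid cell; returns one tidy row per (replicate, method).

    Columns: cell identifiers, ``selected`` (both causal variables at
    VIM ranks 1–2), the two causal ranks, test-set ``ibs`` and
    ``cindex``.  Replicate-level failures are logged and reported with
    an ``error`` note instead of being dropped.
    """
    records = []
    for rep in range(reps):
        ss = replicate_rng(master_seed, spec, rep)
        rng = np.random.default_rng(ss)
        sub_seeds = ss.generate_state(len(methods) + 1)
        train, test = make_replicate(spec, rng)
        cat = train.categorical_features() or None
        for m_idx, method in enumerate(methods):
            rec = _record_base(spec, method, rep)
            try:
                forest = METHODS[method](
                    n_trees=n_trees, mtry=mtry, categorical_features=cat,
                    random_state=int(sub_seeds[m_idx]),
                ).fit(train.X, train.y)
                vim = permutation_importance(
                    forest, n_perm=n_perm, random_state=int(sub_seeds[-1])
                )
                ranks = vim["rank"].to_numpy()
                r1, r2 = (int(ranks[c]) for c in train.causal_ids)
                rec.update(selected=int(max(r1, r2) <= 2), rank1=r1, rank2=r2)
                if evaluate_test:
                    ev = evaluate_predictions(forest, test.X, test.y)
                    rec.update(ibs=ev["ibs"], cindex=ev["cindex"])
                else:
                    rec.update(ibs=np.nan, cindex=np.nan)
                rec["error"] = ""
            except Exception as exc:  # noqa: BLE001 - reported, not dropped
                logger.warning("replicate %d (%s) failed: %s", rep, method, exc)
                rec.update(selected=np.nan, rank1=np.nan, rank2=np.nan,
                           ibs=np.nan, cindex=np.nan, error=str(exc))
            records.append(rec)
    return pd.DataFrame.from_records(records)


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-replicate records into one row per (cell, method).

    Selection frequency comes with a binomial standard error, IBS and
    c-index means with empirical standard errors.
    """
    if records.empty:
        return pd.DataFrame(columns=_CELL_KEYS)

    def _agg(g: pd.DataFrame) -> pd.Series:
        sel = g["selected"].dropna()
        n = len(sel)
        p = sel.mean() if n else np.nan
        ibs = g["ibs"].dropna()
        ci = g["cindex"].dropna()
        return pd.Series({
            "reps": n,
            "selection_freq": p,
            "selection_se": np.sqrt(p * (1 - p) / n) if n else np.nan,
            "mean_ibs": ibs.mean() if len(ibs) else np.nan,
            "ibs_se": ibs.std(ddof=1) / np.sqrt(len(ibs)) if len(ibs) > 1 else np.nan,
            "mean_cindex": ci.mean() if len(ci) else np.nan,
            "cindex_se": ci.std(ddof=1) / np.sqrt(len(ci)) if len(ci) > 1 else np.nan,
            "failures": int((g["error"] != "").sum()),
        })

    grouped = records.groupby(_CELL_KEYS, dropna=False).apply(_agg, include_groups=False)
    return grouped.reset_index()


def selection_frequencies(records: pd.DataFrame) -> dict:
    """Per-method selection frequency of a single-cell record table."""
    out = {}
    for method, g in records.groupby("method"):
        sel = g["selected"].dropna()
        out[method] = float(sel.mean()) if len(sel) else float("nan")
    return out


def load_survival_csv(path, categorical=()):
    """Read a ``time,status,covariates`` CSV, excluding rows with missing
    values (the count is logged)."""
    df = pd.read_csv(path)
    n0 = len(df)
    df = df.dropna()
    dropped = n0 - len(df)
    if dropped:
        logger.info("excluded %d of %d rows with missing values", dropped, n0)
    return SurvivalDataset.from_frame(df.reset_index(drop=True), categorical=categorical)


def run_real_data(csv_path, categorical=(), methods=("RSF", "CIF", "MSR-RF"),
                  reps=100, master_seed=0, n_trees=200, test_fraction=0.2,
                  include_cox=False):
    """Repeated random 80/20 splits of a real dataset; per-split test IBS.

    Returns a tidy DataFrame (``rep``, ``method``, ``ibs``, ``cindex``)
    ready for boxplots.  With ``include_cox=True`` a proportional-hazards
    benchmark (fitted with lifelines, factors one-hot encoded) is added
    under method name ``"Cox"``.
    """
    data = load_survival_csv(csv_path, categorical=categorical)
    n = len(data)
    n_test = max(1, int(round(test_fraction * n)))
    records = []
    for rep in range(reps):
        ss = np.random.SeedSequence([int(master_seed), rep])
        rng = np.random.default_rng(ss)
        sub_seeds = ss.generate_state(len(methods))
        perm = rng.permutation(n)
        test_idx, train_idx = np.sort(perm[:n_test]), np.sort(perm[n_test:])
        sub = lambda idx: SurvivalDataset(
            data.time[idx], data.event[idx], data.X[idx], data.kinds,
            feature_names=data.feature_names,
        )
        train, test = sub(train_idx), sub(test_idx)
        cat = train.categorical_features() or None
        for m_idx, method in enumerate(methods):
            rec = {"rep": rep, "method": method}
            try:
                forest = METHODS[method](
                    n_trees=n_trees, categorical_features=cat,
                    random_state=int(sub_seeds[m_idx]),
                ).fit(train.X, train.y)
                ev = evaluate_predictions(forest, test.X, test.y)
                rec.update(ibs=ev["ibs"], cindex=ev["cindex"], error="")
            except Exception as exc:  # noqa: BLE001
                logger.warning("real-data rep %d (%s) failed: %s", rep, method, exc)
                rec.update(ibs=np.nan, cindex=np.nan, error=str(exc))
            records.append(rec)
        if include_cox:
            records.append(_cox_benchmark(train, test, rep))
    return pd.DataFrame.from_records(records)


def _cox_benchmark(train, test, rep):
    """Proportional-hazards comparator via lifelines (not a forest)."""
    from lifelines import CoxPHFitter

    from .metrics import brier_curve, censoring_km, evaluation_grid, harrell_c, integrated_brier

    rec = {"rep": rep, "method": "Cox"}
    try:
        def frame(ds):
            df = ds.to_frame()
            factor_cols = [df.columns[2 + j] for j, k in enumerate(ds.kinds) if k >= 2]
            return pd.get_dummies(df, columns=factor_cols, drop_first=True, dtype=float)

        tr, te = frame(train), frame(test)
        te = te.reindex(columns=tr.columns, fill_value=0.0)
        cph = CoxPHFitter(penalizer=0.01).fit(tr, "time", "status")
        G = censoring_km(test.time, test.event)
        grid = evaluation_grid(test.time, test.event, G)
        surv = cph.predict_survival_function(
            te.drop(columns=["time", "status"]), times=grid
        ).to_numpy().T
        _, bs, _ = brier_curve(surv, grid, test.time, test.event, G)
        rec.update(
            ibs=integrated_brier(grid, bs),
            cindex=harrell_c(
                cph.predict_partial_hazard(te.drop(columns=["time", "status"])).to_numpy(),
                test.time, test.event,
            ),
            error="",
        )
    except Exception as exc:  # noqa: BLE001
        logger.warning("Cox benchmark rep %d failed: %s", rep, exc)
        rec.update(ibs=np.nan, cindex=np.nan, error=str(exc))
    return rec
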