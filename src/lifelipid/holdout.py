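"""Clade-elimination robustness protocol.

An increasing fraction of one clade's individuals is moved from the
training set to the test set (10%…90% in 10% steps, plus full removal),
many times per step.  Per replicate, per-tissue elastic-net models are
fitted on the reduced training set, tissue datasets are merged into a
brain (cortex + cerebellum) and a non-neural (liver + muscle + kidney)
dataset by coefficient-ranked feature alignment, and AUC is evaluated on
the held-out clade individuals only.  A label-permutation baseline
provides the chance band.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifiers import (fit_elasticnet_logistic, roc_auc, sample_labels,
                          standardize_columns)
from .datatypes import BRAIN_TISSUES, NONNEURAL_TISSUES, Cohort, PeakTable

DEFAULT_FRACTIONS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


# ---------------------------------------------------------------------------
# coefficient-ranked tissue merging
# ---------------------------------------------------------------------------

def _feature_order(coef: pd.Series, X_train: pd.DataFrame, y_train) -> pd.Index:
    """Features sorted by |coefficient| (desc) then long-vs-short mean
    difference (desc); zero-coefficient, lowest-difference features sort
    last and are the first removed."""
    y = np.asarray(y_train, dtype=bool)
    diff = X_train.loc[:, coef.index][y].mean(axis=0) - X_train.loc[:, coef.index][~y].mean(axis=0)
    key = pd.DataFrame({"absc": coef.abs(), "diff": diff})
    key = key.sort_values(["absc", "diff"], ascending=[False, False], kind="mergesort")
    return key.index


def merge_tissue_datasets(
    Xs: dict, coefs: dict, ys: dict
) -> tuple[pd.DataFrame, np.ndarray, dict, int]:
    """Merge per-tissue datasets into one rank-aligned matrix.

    Per tissue, features are ordered by (|coefficient| desc, long-short
    mean difference desc); zero-coefficient features beyond the nonzero
    count are removed, and all tissues are trimmed to the minimum
    post-removal width.  Equal-width tables are then aligned by rank
    position and stacked row-wise (samples from every tissue).

    Returns (merged X with rank columns, stacked y, per-tissue feature
    order used, width).
    """
    orders, widths = {}, {}
    for t in Xs:
        nz = int((coefs[t] != 0).sum())
        if nz == 0:
            raise ValueError(f"tissue {t!r} has no nonzero-coefficient features")
        orders[t] = _feature_order(coefs[t], Xs[t], ys[t])
        widths[t] = nz
    w = min(widths.values())
    blocks, labels = [], []
    for t in sorted(Xs):
        cols = orders[t][:w]
        block = Xs[t].loc[:, cols].to_numpy(dtype=float)
        blocks.append(pd.DataFrame(block, columns=[f"rank{i}" for i in range(w)],
                                   index=Xs[t].index))
        labels.append(np.asarray(ys[t], dtype=int))
    merged = pd.concat(blocks, axis=0)
    return merged, np.concatenate(labels), {t: orders[t][:w] for t in Xs}, w


def apply_merge_order(Xs: dict, orders: dict) -> tuple[pd.DataFrame, list]:
    """Stack test-set tissue tables with a previously computed order."""
    blocks, idx = [], []
    w = len(next(iter(orders.values())))
    for t in sorted(Xs):
        cols = orders[t]
        block = Xs[t].loc[:, cols].to_numpy(dtype=float)
        blocks.append(pd.DataFrame(block, columns=[f"rank{i}" for i in range(w)],
                                   index=Xs[t].index))
        idx.extend(Xs[t].index)
    return pd.concat(blocks, axis=0), idx


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

def random_baseline(
    X, y, alpha: float = 0.5, lam: float = 0.03,
    n_rand: int = 100, seed: int = 0,
    X_test=None, y_test=None, folds: int = 4,
) -> dict:
    """Chance-level AUC by randomizing the output variable ``n_rand`` times.

    With a test split given, each permutation shuffles the training
    labels, refits, and evaluates against the true test labels
    (the gray band of the clade-elimination figure).  Without one, each
    permutation shuffles all labels and the AUC is the stratified
    ``folds``-fold CV mean under that permutation.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    aucs = []
    for _ in range(n_rand):
        yp = rng.permutation(y)
        if X_test is not None:
            if len(np.unique(yp)) < 2:
                continue
            Z, mean, sd = standardize_columns(X)
            m = fit_elasticnet_logistic(Z, yp, alpha, lam, tol=1e-4, max_iter=2000)
            Zt, _, _ = standardize_columns(np.asarray(X_test, dtype=float), mean, sd)
            aucs.append(roc_auc(y_test, Zt @ m.coef.to_numpy() + m.intercept))
        else:
            from sklearn.model_selection import StratifiedKFold
            if min(np.bincount(yp)) < folds:
                k = max(2, min(folds, min(np.bincount(yp))))
            else:
                k = folds
            skf = StratifiedKFold(n_splits=k, shuffle=True,
                                  random_state=int(rng.integers(2**31)))
            fold_aucs = []
            for tr, te in skf.split(X, yp):
                if len(np.unique(yp[te])) < 2 or len(np.unique(yp[tr])) < 2:
                    continue
                Z, mean, sd = standardize_columns(X[tr])
                m = fit_elasticnet_logistic(Z, yp[tr], alpha, lam, tol=1e-4,
                                            max_iter=2000)
                Zt, _, _ = standardize_columns(X[te], mean, sd)
                fold_aucs.append(roc_auc(yp[te], Zt @ m.coef.to_numpy() + m.intercept))
            if fold_aucs:
                aucs.append(float(np.mean(fold_aucs)))
    aucs = np.asarray(aucs, dtype=float)
    return {"mean_auc": float(aucs.mean()), "sd_auc": float(aucs.std(ddof=1)),
            "aucs": aucs}


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------

def _held_individuals(cohort: Cohort, clade: str, fraction: float, rng) -> list:
    """Sample clade individuals, stratified by long/short status so the
    held-out set always contains both classes."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    lab = sample_labels(cohort, cohort.samples.index)
    meta = cohort.samples.assign(long=lab)
    meta = meta[cohort.species.loc[meta["species_id"], "clade"].to_numpy() == clade]
    if meta.empty:
        raise ValueError(f"clade {clade!r} absent from the cohort")
    held = []
    for flag in (True, False):
        inds = sorted(meta.loc[meta["long"] == flag, "individual_id"].unique())
        k = len(inds) if fraction >= 1.0 else max(1, int(round(fraction * len(inds))))
        held.extend(rng.choice(inds, size=k, replace=False))
    return sorted(held)


def run_clade_elimination(
    tables: dict,
    cohort: Cohort,
    clade: str,
    fractions=DEFAULT_FRACTIONS,
    reps: int = 100,
    alpha: float = 0.5,
    lam: float = 0.03,
    seed: int = 0,
    fit_tol: float = 1e-4,
    fit_max_iter: int = 2000,
) -> pd.DataFrame:
    """Graded clade removal with per-tissue and merged-dataset evaluation.

    ``tables`` maps tissue → log-scale imputed :class:`PeakTable`.
    Returns a tidy frame (clade, fraction, replicate, dataset, auc) with
    one row per tissue plus 'brain' and 'nonneural' merged datasets.
    """
    labels = {t: sample_labels(cohort, tab.sample_ids) for t, tab in tables.items()}
    rows = []
    for fi, fraction in enumerate(fractions):
        for rep in range(reps):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, fi, rep]))
            held = set(_held_individuals(cohort, clade, fraction, rng))
            coefs, Xtr_all, Xte_all, ytr_all, yte_all = {}, {}, {}, {}, {}
            for t, tab in tables.items():
                ind = cohort.samples.loc[tab.sample_ids, "individual_id"]
                te_mask = ind.isin(held).to_numpy()
                Xtr = tab.values.loc[~te_mask]
                Xte = tab.values.loc[te_mask]
                ytr = labels[t].loc[~te_mask].to_numpy().astype(int)
                yte = labels[t].loc[te_mask].to_numpy().astype(int)
                # leakage audit: training never sees held individuals
                assert not set(cohort.samples.loc[Xtr.index, "individual_id"]) & held
                Z, mean, sd = standardize_columns(Xtr.to_numpy(dtype=float))
                m = fit_elasticnet_logistic(Z, ytr, alpha, lam,
                                            feature_ids=Xtr.columns,
                                            tol=fit_tol, max_iter=fit_max_iter)
                Zt, _, _ = standardize_columns(Xte.to_numpy(dtype=float), mean, sd)
                scores = Zt @ m.coef.to_numpy() + m.intercept
                auc = roc_auc(yte, scores) if len(np.unique(yte)) == 2 else np.nan
                rows.append({"clade": clade, "fraction": fraction, "replicate": rep,
                             "dataset": t, "auc": auc})
                coefs[t] = m.coef
                Xtr_all[t], Xte_all[t] = Xtr, Xte
                ytr_all[t], yte_all[t] = ytr, yte
            for name, group in (("brain", BRAIN_TISSUES), ("nonneural", NONNEURAL_TISSUES)):
                sub = [t for t in group if t in tables]
                if len(sub) < 2:
                    continue
                Xm, ym, orders, _ = merge_tissue_datasets(
                    {t: Xtr_all[t] for t in sub}, {t: coefs[t] for t in sub},
                    {t: ytr_all[t] for t in sub})
                Xmt, _ = apply_merge_order({t: Xte_all[t] for t in sub}, orders)
                ymt = np.concatenate([yte_all[t] for t in sorted(sub)])
                Z, mean, sd = standardize_columns(Xm.to_numpy(dtype=float))
                m = fit_elasticnet_logistic(Z, ym, alpha, lam,
                                            tol=fit_tol, max_iter=fit_max_iter)
                Zt, _, _ = standardize_columns(Xmt.to_numpy(dtype=float), mean, sd)
                scores = Zt @ m.coef.to_numpy() + m.intercept
                auc = roc_auc(ymt, scores) if len(np.unique(ymt)) == 2 else np.nan
                rows.append({"clade": clade, "fraction": fraction, "replicate": rep,
                             "dataset": name, "auc": auc})
    return pd.DataFrame(rows)


def summarize_elimination(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and MC standard error of AUC per (dataset, fraction)."""
    g = results.groupby(["dataset", "fraction"])["auc"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out["se"] = out["std"] / np.sqrt(out["count"].clip(lower=1))
    return out
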