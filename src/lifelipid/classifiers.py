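"""Penalized longevity classifiers.

The central model distinguishes long-living species (MLS above 0.9 × the
clade maximum) from all others based on per-tissue lipid concentrations,
using logistic regression with an elastic-net penalty.  The fitted
objective, on standardized features, is::

    mean_i NLL(y_i, b0 + x_i·b) + lam * [ (1-alpha)/2 * ||b||² + alpha * ||b||₁ ]

with an unpenalized intercept.  The mixing parameter ``alpha`` (and the
penalty strength ``lam``) are chosen by stratified 10 × 10
cross-validated AUC, where AUC is computed as the Mann–Whitney
concordance of held-out scores.  Lipids with nonzero coefficients in the
full-data refit are the *MLS predictors*.

Two alternative models mirror the comparison analyses: a linear-kernel
SVM with recursive feature elimination (1% of features removed per step
down to 10), and a linear elastic net regressing clade-normalized MLS.

The module is organised statsmodels-style: :class:`LongevityClassifier`
is the model, its ``fit``/``fit_cv`` return :class:`LongevityResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .datatypes import Cohort, PeakTable

DEFAULT_ALPHA_GRID = (0.2, 0.5, 0.8)
DEFAULT_LAM_GRID = (0.3, 0.1, 0.03, 0.01, 0.003)


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def label_long_living(species: pd.DataFrame) -> pd.DataFrame:
    """Long-living labels: MLS strictly above 0.9 × the clade maximum.

    The clade-maximum species is always labeled long-living.  Returns a
    frame indexed by species_id with clade, mls, clade_max_mls,
    threshold, is_long_living.
    """
    if species["mls"].isna().any():
        raise ValueError("species with missing MLS")
    out = species[["clade", "mls"]].copy()
    out["clade_max_mls"] = out.groupby("clade")["mls"].transform("max")
    out["threshold"] = 0.9 * out["clade_max_mls"]
    out["is_long_living"] = out["mls"] > out["threshold"]
    return out


def sample_labels(cohort: Cohort, sample_ids) -> pd.Series:
    """Boolean long-living label per sample."""
    lab = label_long_living(cohort.species)["is_long_living"]
    sp = cohort.samples.loc[sample_ids, "species_id"]
    return lab.loc[sp].set_axis(pd.Index(sample_ids)).rename("is_long_living")


# ---------------------------------------------------------------------------
# AUC = Mann–Whitney concordance
# ---------------------------------------------------------------------------

def roc_auc(y_true, scores) -> float:
    """Area under the ROC curve via midrank concordance.

    Equals the probability that a positive sample outranks a negative
    one (rank-sum statistic / (n1·n0)), ties counted half.
    """
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required to compute AUC")
    r = stats.rankdata(s)
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize_columns(X: np.ndarray, mean=None, sd=None):
    """Column z-scoring; constant columns map to zero."""
    X = np.asarray(X, dtype=float)
    if mean is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / safe
    Z[:, sd == 0] = 0.0
    return Z, mean, sd


# ---------------------------------------------------------------------------
# elastic-net logistic core
# ---------------------------------------------------------------------------

@dataclass
class PredictorModel:
    """Fitted penalized model and its selected predictor set."""

    alpha: float
    lam: float
    intercept: float
    coef: pd.Series
    cv_auc: float = np.nan
    kind: str = "logistic"
    feature_mean: np.ndarray | None = None
    feature_sd: np.ndarray | None = None

    @property
    def selected_peaks(self) -> list:
        return list(self.coef.index[self.coef != 0.0])

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        Z = X[self.coef.index].to_numpy(dtype=float)
        if self.feature_mean is not None:
            Z, _, _ = standardize_columns(Z, self.feature_mean, self.feature_sd)
        return self.intercept + Z @ self.coef.to_numpy()

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha, "lam": self.lam, "intercept": self.intercept,
            "cv_auc": None if np.isnan(self.cv_auc) else self.cv_auc,
            "kind": self.kind,
            "coef": {k: float(v) for k, v in self.coef.items() if v != 0.0},
        }


def _sk_logistic(alpha: float, lam: float, n: int, tol: float, max_iter: int):
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return LogisticRegression(
        penalty="elasticnet", solver="saga", l1_ratio=alpha,
        C=1.0 / (n * lam), tol=tol, max_iter=max_iter, random_state=0,
    )


def fit_elasticnet_logistic(
    X, y, alpha: float, lam: float,
    feature_ids=None, tol: float = 1e-7, max_iter: int = 20000,
) -> PredictorModel:
    """Fit the elastic-net logistic model on (already standardized) X.

    ``lam`` is the penalty strength of the mean-log-likelihood objective
    above; it maps onto scikit-learn's saga solver via C = 1/(n·lam).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if feature_ids is None:
        feature_ids = pd.RangeIndex(X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = _sk_logistic(alpha, lam, len(y), tol, max_iter).fit(X, y)
    b0 = _refine_intercept(X, y, float(est.intercept_[0]), est.coef_[0])
    return PredictorModel(
        alpha=float(alpha), lam=float(lam),
        intercept=b0,
        coef=pd.Series(est.coef_[0], index=pd.Index(feature_ids)),
    )


def _refine_intercept(X, y, b0: float, coef, tol: float = 1e-12,
                      max_iter: int = 100) -> float:
    """Newton polish of the unpenalized intercept at fixed coefficients.

    The saga solver's stopping rule watches the penalized weights only,
    so the intercept can lag behind when the coefficients are already
    stationary (e.g. under full shrinkage)."""
    eta0 = X @ np.asarray(coef, dtype=float)
    ybar = np.mean(y)
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-(b0 + eta0)))
        g = p.mean() - ybar
        if abs(g) < tol:
            break
        h = np.mean(p * (1.0 - p))
        if h <= 0:
            break
        b0 -= g / h
    return float(b0)


def en_logistic_objective(X, y, intercept: float, coef, alpha: float, lam: float) -> float:
    """Mean negative Bernoulli log-likelihood + elastic-net penalty."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    b = np.asarray(coef, dtype=float)
    eta = intercept + X @ b
    nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
    pen = lam * ((1.0 - alpha) / 2.0 * np.sum(b**2) + alpha * np.sum(np.abs(b)))
    return float(nll + pen)


def en_logistic_kkt_gap(X, y, intercept: float, coef, alpha: float, lam: float) -> float:
    """Largest violation of the subgradient optimality conditions."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    b = np.asarray(coef, dtype=float)
    eta = intercept + X @ b
    p = 1.0 / (1.0 + np.exp(-eta))
    g = X.T @ (p - y) / len(y) + lam * (1.0 - alpha) * b
    gap = abs(np.mean(p - y))  # intercept condition
    nz = b != 0
    if nz.any():
        gap = max(gap, np.max(np.abs(g[nz] + lam * alpha * np.sign(b[nz]))))
    if (~nz).any():
        gap = max(gap, np.max(np.clip(np.abs(g[~nz]) - lam * alpha, 0.0, None)))
    return float(gap)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    best_alpha: float
    best_lam: float
    mean_auc: float
    fold_aucs: np.ndarray  # (repeats*folds,) for the best combination
    grid: pd.DataFrame     # alpha, lam, mean_auc


def _cv_splits(y, folds, repeats, seed, max_redraw=20):
    """Stratified fold assignments; folds with one class are re-drawn."""
    y = np.asarray(y, dtype=int)
    splits = []
    draw = 0
    rep = 0
    while rep < repeats:
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=(seed + 1000 * rep + draw) % (2**31))
        cand = list(skf.split(np.zeros(len(y)), y))
        if any(len(np.unique(y[te])) < 2 for _, te in cand):
            draw += 1
            if draw > max_redraw:
                raise ValueError("could not stratify folds with both classes")
            warnings.warn("re-drawing a fold with a single class")
            continue
        splits.extend(cand)
        rep += 1
    return splits


def cross_validate(
    X, y,
    alpha_grid=DEFAULT_ALPHA_GRID,
    lam_grid=DEFAULT_LAM_GRID,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 2000,
) -> CVResult:
    """Stratified repeated CV over the (alpha, lam) grid.

    Every combination is scored on the same fold draws; per alpha the
    lam path is fit warm-started from the strongest penalty down.  The
    reported AUC of a combination is the mean over the
    ``folds × repeats`` held-out folds.  Ties are broken toward smaller
    lam (denser model) then smaller alpha.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if min(np.bincount(y)) < 2:
        raise ValueError("need >= 2 samples per class")
    splits = _cv_splits(y, folds, repeats, seed)
    lam_desc = sorted(lam_grid, reverse=True)
    combos = [(a, l) for a in alpha_grid for l in lam_grid]
    cidx = {c: i for i, c in enumerate(combos)}
    aucs = np.zeros((len(combos), len(splits)))
    for si, (tr, te) in enumerate(splits):
        Ztr, mean, sd = standardize_columns(X[tr])
        Zte, _, _ = standardize_columns(X[te], mean, sd)
        for a in alpha_grid:
            est = _sk_logistic(a, lam_desc[0], len(tr), tol, max_iter)
            est.warm_start = True
            for l in lam_desc:
                est.C = 1.0 / (len(tr) * l)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(Ztr, y[tr])
                scores = Zte @ est.coef_[0] + est.intercept_[0]
                aucs[cidx[(a, l)], si] = roc_auc(y[te], scores)
    mean_aucs = aucs.mean(axis=1)
    order = sorted(
        range(len(combos)),
        key=lambda c: (-mean_aucs[c], combos[c][1], combos[c][0]),
    )
    best = order[0]
    grid = pd.DataFrame(
        [(a, l, m) for (a, l), m in zip(combos, mean_aucs)],
        columns=["alpha", "lam", "mean_auc"],
    )
    return CVResult(
        best_alpha=float(combos[best][0]),
        best_lam=float(combos[best][1]),
        mean_auc=float(mean_aucs[best]),
        fold_aucs=aucs[best],
        grid=grid,
    )


def select_predictors(X, y, alpha: float, lam: float, feature_ids=None) -> PredictorModel:
    """Refit on all samples at (alpha, lam); predictors are the peaks with
    nonzero coefficients."""
    Z, mean, sd = standardize_columns(np.asarray(X, dtype=float))
    model = fit_elasticnet_logistic(Z, y, alpha, lam, feature_ids=feature_ids)
    model.feature_mean, model.feature_sd = mean, sd
    return model


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class LongevityClassifier:
    """Elastic-net logistic model of long-living status from a peak table.

    Parameters
    ----------
    X : DataFrame
        Samples × peaks log-concentration matrix (imputed).
    y : array-like of bool
        Long-living label per sample.
    """

    def __init__(self, X: pd.DataFrame, y):
        self.X = X
        self.y = np.asarray(y, dtype=int)
        if len(self.y) != len(X):
            raise ValueError("label length mismatch")

    @classmethod
    def from_table(cls, table: PeakTable, cohort: Cohort) -> "LongevityClassifier":
        y = sample_labels(cohort, table.sample_ids)
        return cls(table.values, y.to_numpy())

    def fit(self, alpha: float = 0.5, lam: float = 0.03) -> "LongevityResults":
        model = select_predictors(self.X.to_numpy(dtype=float), self.y, alpha, lam,
                                  feature_ids=self.X.columns)
        return LongevityResults(self, model, cv=None)

    def fit_cv(
        self,
        alpha_grid=DEFAULT_ALPHA_GRID,
        lam_grid=DEFAULT_LAM_GRID,
        folds: int = 10,
        repeats: int = 10,
        seed: int = 0,
    ) -> "LongevityResults":
        cv = cross_validate(self.X.to_numpy(dtype=float), self.y, alpha_grid,
                            lam_grid, folds=folds, repeats=repeats, seed=seed)
        model = select_predictors(self.X.to_numpy(dtype=float), self.y,
                                  cv.best_alpha, cv.best_lam,
                                  feature_ids=self.X.columns)
        model.cv_auc = cv.mean_auc
        return LongevityResults(self, model, cv=cv)


@dataclass
class LongevityResults:
    """Fit results: coefficients, CV accuracy, selected predictor peaks."""

    model_spec: LongevityClassifier
    model: PredictorModel
    cv: CVResult | None = None

    @property
    def params(self) -> pd.Series:
        return self.model.coef

    @property
    def selected_peaks(self) -> list:
        return self.model.selected_peaks

    @property
    def cv_auc(self) -> float:
        return self.model.cv_auc

    @property
    def predictor_fraction(self) -> float:
        return len(self.selected_peaks) / max(1, len(self.model.coef))

    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.decision_scores(X)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Longevity elastic-net classifier",
            "=" * 40,
            f"n samples:          {len(self.model_spec.y)}",
            f"n peaks:            {len(m.coef)}",
            f"positives:          {int(self.model_spec.y.sum())}",
            f"alpha (mixing):     {m.alpha:.3f}",
            f"lambda (penalty):   {m.lam:.4f}",
            f"cv AUC:             {m.cv_auc:.3f}" if not np.isnan(m.cv_auc)
            else "cv AUC:             (not cross-validated)",
            f"selected peaks:     {len(m.selected_peaks)}"
            f" ({100 * self.predictor_fraction:.1f}% of peaks)",
            "-" * 40,
            "largest coefficients:",
        ]
        top = m.coef[m.coef != 0].abs().sort_values(ascending=False).head(10)
        for pid in top.index:
            lines.append(f"  {pid:<14} {m.coef[pid]:+10.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# SVM-RFE
# ---------------------------------------------------------------------------

def _rfe_path(Z, y, step_fraction, min_features, C=1.0):
    """Feature subsets visited by recursive elimination on all of (Z, y)."""
    n_total = Z.shape[1]
    step = max(1, int(np.ceil(step_fraction * n_total)))
    active = np.arange(n_total)
    path = [active.copy()]
    while len(active) > min_features:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            svm = LinearSVC(C=C, dual=True, max_iter=20000, random_state=0)
            svm.fit(Z[:, active], y)
        w = np.abs(svm.coef_[0])
        k = min(step, len(active) - min_features)
        # lowest |coefficient| removed first; ties by column index
        drop = np.lexsort((active, w))[:k]
        active = np.delete(active, drop)
        path.append(active.copy())
    return path


def svm_rfe(
    X, y,
    step_fraction: float = 0.01,
    min_features: int = 10,
    folds: int = 5,
    repeats: int = 2,
    seed: int = 0,
    feature_ids=None,
) -> dict:
    """Linear-SVM recursive feature elimination.

    Per CV run, 1% of the initial feature count (at least one feature,
    ranked by |coefficient|) is removed per iteration until at most
    ``min_features`` remain; the feature count with the best mean
    held-out AUC is chosen, and the final model is re-trained on all
    data down to that count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if min_features > X.shape[1]:
        raise ValueError("min_features exceeds the feature count")
    if feature_ids is None:
        feature_ids = pd.RangeIndex(X.shape[1])
    feature_ids = pd.Index(feature_ids)
    splits = _cv_splits(y, folds, repeats, seed)
    sizes = [len(a) for a in _rfe_path(X, y, step_fraction, min_features)]
    acc = {n: [] for n in sizes}
    for tr, te in splits:
        Ztr, mean, sd = standardize_columns(X[tr])
        Zte, _, _ = standardize_columns(X[te], mean, sd)
        for active in _rfe_path(Ztr, y[tr], step_fraction, min_features):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                svm = LinearSVC(dual=True, max_iter=20000, random_state=0)
                svm.fit(Ztr[:, active], y[tr])
            scores = Zte[:, active] @ svm.coef_[0] + svm.intercept_[0]
            acc.setdefault(len(active), []).append(roc_auc(y[te], scores))
    mean_acc = {n: float(np.mean(v)) for n, v in acc.items() if v}
    best_n = min(mean_acc, key=lambda n: (-mean_acc[n], n))
    Z, _, _ = standardize_columns(X)
    final = None
    for active in _rfe_path(Z, y, step_fraction, min_features):
        if len(active) <= best_n:
            final = active
            break
    if final is None:
        final = _rfe_path(Z, y, step_fraction, min_features)[-1]
    return {
        "n_features": int(best_n),
        "features": list(feature_ids[final]),
        "accuracy": mean_acc[best_n],
        "accuracy_path": mean_acc,
    }


# ---------------------------------------------------------------------------
# linear elastic net on clade-normalized MLS
# ---------------------------------------------------------------------------

def normalized_mls(cohort: Cohort, sample_ids) -> pd.Series:
    """Species MLS divided by its clade maximum, broadcast to samples.

    The clade-maximum species gets exactly 1.0.
    """
    sp = cohort.species
    clade_max = sp.groupby("clade")["mls"].transform("max")
    if (clade_max <= 0).any():
        raise ValueError("clade with non-positive maximal MLS")
    norm = sp["mls"] / clade_max
    sids = cohort.samples.loc[sample_ids, "species_id"]
    return norm.loc[sids].set_axis(pd.Index(sample_ids)).rename("mls_norm")


def fit_elasticnet_linear(
    X, y_mls_norm, alpha: float = 0.5, lam: float = 0.03,
    feature_ids=None, tol: float = 1e-7, max_iter: int = 20000,
) -> PredictorModel:
    """Linear elastic net with squared-error loss on clade-normalized MLS.

    Objective: ``1/(2n)·||y − b0 − X·b||² + lam·[(1−alpha)/2·||b||² +
    alpha·||b||₁]`` (scikit-learn's ElasticNet parametrization with
    ``alpha_sk = lam`` and ``l1_ratio = alpha``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_mls_norm, dtype=float)
    if feature_ids is None:
        feature_ids = pd.RangeIndex(X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = ElasticNet(alpha=lam, l1_ratio=alpha, tol=tol, max_iter=max_iter)
        est.fit(X, y)
    return PredictorModel(
        alpha=float(alpha), lam=float(lam), intercept=float(est.intercept_),
        coef=pd.Series(est.coef_, index=pd.Index(feature_ids)), kind="linear",
    )


def en_linear_objective(X, y, intercept: float, coef, alpha: float, lam: float) -> float:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    b = np.asarray(coef, dtype=float)
    resid = y - intercept - X @ b
    loss = 0.5 * np.mean(resid**2)
    pen = lam * ((1.0 - alpha) / 2.0 * np.sum(b**2) + alpha * np.sum(np.abs(b)))
    return float(loss + pen)
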