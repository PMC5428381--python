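"""Confounder association tests and permutation-based family-wise
multiple-testing correction.

Lipid concentrations may track species traits (basal metabolic rate,
body mass, body temperature, diet, hibernation) or individual traits
(sex, age) rather than longevity itself.  Each factor is tested with the
appropriate statistic — Welch t-test for two-level factors, one-way
ANOVA for diet, simple linear regression for continuous traits — and the
raw p-values are corrected by the Westfall–Young maxT permutation scheme
(step-down, add-one estimator).  Species-level factors are tested
against per-species mean concentrations to avoid pseudoreplication;
sex and age are tested at the sample level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import Cohort, PeakTable

#: factor -> (observation level, test kind)
FACTOR_SPECS = {
    "sex": ("sample", "binary"),
    "hibernation": ("species", "binary"),
    "diet": ("species", "anova"),
    "bmr": ("species", "linreg"),
    "body_temp": ("species", "linreg"),
    "body_mass": ("species", "linreg"),
    "age": ("sample", "linreg"),
}

_FACTOR_COLUMN = {"hibernation": "hibernates", "bmr": "bmr", "body_temp": "body_temp",
                  "body_mass": "body_mass", "diet": "diet", "sex": "sex", "age": "age"}


# ---------------------------------------------------------------------------
# design extraction
# ---------------------------------------------------------------------------

def _design(table: PeakTable, cohort: Cohort, factor: str):
    """Return (Y units×peaks, x per unit, kind) for a factor."""
    if factor not in FACTOR_SPECS:
        raise KeyError(f"unknown factor {factor!r}")
    level, kind = FACTOR_SPECS[factor]
    col = _FACTOR_COLUMN[factor]
    samples = cohort.samples.loc[table.sample_ids]
    if level == "sample":
        Y = table.values.to_numpy(dtype=float)
        x = samples[col]
    else:
        sp = samples["species_id"].to_numpy()
        Ydf = table.values.groupby(sp).mean()
        Y = Ydf.to_numpy(dtype=float)
        x = cohort.species.loc[Ydf.index, col]
    if kind == "binary":
        x = pd.Series(x).astype("category")
        if x.cat.categories.size > 2:
            raise ValueError(f"factor {factor!r} has more than two levels")
        xv = x.cat.codes.to_numpy(dtype=float)
    elif kind == "anova":
        xv = pd.Categorical(x).codes.astype(float)
    else:
        xv = np.asarray(x, dtype=float)
        if factor in ("bmr", "body_mass"):
            xv = np.log(xv)  # allometric traits are tested on log scale
    return Y, xv, kind


# ---------------------------------------------------------------------------
# vectorized statistics (columns of G are permutations of the factor)
# ---------------------------------------------------------------------------

def _welch_t_batch(Y: np.ndarray, G: np.ndarray) -> np.ndarray:
    """|Welch t| for every (permutation, peak); G is units×B of 0/1."""
    n1 = G.sum(axis=0)
    n0 = G.shape[0] - n1
    s1 = G.T @ Y
    s0 = Y.sum(axis=0)[None, :] - s1
    q1 = G.T @ (Y * Y)
    q0 = (Y * Y).sum(axis=0)[None, :] - q1
    m1 = s1 / n1[:, None]
    m0 = s0 / n0[:, None]
    v1 = (q1 - n1[:, None] * m1**2) / (n1[:, None] - 1)
    v0 = (q0 - n0[:, None] * m0**2) / (n0[:, None] - 1)
    v1 = np.clip(v1, 0.0, None)
    v0 = np.clip(v0, 0.0, None)
    se = np.sqrt(v1 / n1[:, None] + v0 / n0[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m0) / se, 0.0)
    return np.abs(t)


def _welch_df(Y: np.ndarray, g: np.ndarray) -> np.ndarray:
    n1 = int(g.sum())
    n0 = len(g) - n1
    y1, y0 = Y[g.astype(bool)], Y[~g.astype(bool)]
    v1 = y1.var(axis=0, ddof=1) / n1
    v0 = y0.var(axis=0, ddof=1) / n0
    num = (v1 + v0) ** 2
    den = v1**2 / (n1 - 1) + v0**2 / (n0 - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = np.where(den > 0, num / den, n1 + n0 - 2)
    return df


def _anova_f_batch(Y: np.ndarray, C: np.ndarray, k: int) -> np.ndarray:
    """One-way F for every (permutation, peak); C is units×B of level codes."""
    n = Y.shape[0]
    grand = Y.mean(axis=0)
    sst = ((Y - grand) ** 2).sum(axis=0)
    ssb = np.zeros((C.shape[1], Y.shape[1]))
    for lvl in range(k):
        G = (C == lvl).astype(float)
        n_l = G.sum(axis=0)
        m_l = (G.T @ Y) / n_l[:, None]
        ssb += n_l[:, None] * (m_l - grand[None, :]) ** 2
    ssw = np.clip(sst[None, :] - ssb, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    return np.where(np.isfinite(f), f, 0.0)


def _slope_f_batch(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Regression-slope F for every (permutation, peak); X is units×B."""
    n = Y.shape[0]
    Ys = Y - Y.mean(axis=0)
    sdy = Ys.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Ys = np.where(sdy > 0, Ys / sdy, 0.0)
    Xs = X - X.mean(axis=0)
    sdx = Xs.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Xs = np.where(sdx > 0, Xs / sdx, 0.0)
    r = (Xs.T @ Ys) / n
    r = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
    return (n - 2) * r**2 / (1.0 - r**2)


def _observed(Y: np.ndarray, x: np.ndarray, kind: str):
    """Observed statistic magnitude and two-sided raw p per peak."""
    n = Y.shape[0]
    if np.unique(x).size < 2:
        m = Y.shape[1]
        return np.zeros(m), np.ones(m), True
    if kind == "binary":
        stat = _welch_t_batch(Y, x[:, None].astype(float))[0]
        df = _welch_df(Y, x)
        p = 2.0 * stats.t.sf(stat, df)
    elif kind == "anova":
        k = int(x.max()) + 1
        stat = _anova_f_batch(Y, x[:, None].astype(int), k)[0]
        p = stats.f.sf(stat, k - 1, n - k)
    else:
        stat = _slope_f_batch(Y, x[:, None].astype(float))[0]
        p = stats.f.sf(stat, 1, n - 2)
    return stat, np.minimum(p, 1.0), False


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def factor_association(table: PeakTable, cohort: Cohort, factor: str) -> pd.DataFrame:
    """Raw association test of every peak against one factor.

    Returns a DataFrame with peak_id, factor, statistic (|t| or F),
    raw_p, degenerate.  A constant factor yields p = 1 with the
    degenerate flag set.
    """
    Y, x, kind = _design(table, cohort, factor)
    stat, p, degen = _observed(Y, x, kind)
    return pd.DataFrame({
        "peak_id": table.peak_ids,
        "factor": factor,
        "statistic": stat,
        "raw_p": p,
        "degenerate": degen,
    })


def permutation_correct(
    table: PeakTable,
    cohort: Cohort,
    factor: str,
    n_perm: int = 1000,
    seed: int | None = None,
    results: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Westfall–Young maxT step-down corrected p-values for one factor.

    Factor values are permuted across the observation units (species or
    samples) ``n_perm`` times.  With the observed statistics ordered
    decreasingly, the corrected p of the i-th hypothesis uses the
    permutation distribution of the maximum statistic over hypotheses
    ranked i..m, with the add-one estimator
    ``(1 + #{perm ≥ observed}) / (n_perm + 1)``; monotonicity down the
    ordering is enforced.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if results is None:
        results = factor_association(table, cohort, factor)
    out = results.copy()
    if bool(results["degenerate"].iloc[0]):
        out["corrected_p"] = 1.0
        return out

    Y, x, kind = _design(table, cohort, factor)
    rng = np.random.default_rng(seed)
    n = len(x)
    P = np.empty((n, n_perm), dtype=float)
    for b in range(n_perm):
        P[:, b] = x[rng.permutation(n)]

    if kind == "binary":
        S = _welch_t_batch(Y, P)
    elif kind == "anova":
        S = _anova_f_batch(Y, P.astype(int), int(x.max()) + 1)
    else:
        S = _slope_f_batch(Y, P)

    obs = results["statistic"].to_numpy()
    order = np.argsort(-obs, kind="mergesort")
    S_ord = S[:, order]
    # successive maxima over hypotheses ranked i..m (step-down)
    q = np.maximum.accumulate(S_ord[:, ::-1], axis=1)[:, ::-1]
    exceed = (q >= obs[order][None, :]).sum(axis=0)
    p_ord = (1.0 + exceed) / (n_perm + 1.0)
    p_ord = np.maximum.accumulate(p_ord)  # enforce monotone step-down
    corrected = np.empty_like(p_ord)
    corrected[order] = p_ord
    # the correction can only inflate the analytic raw p
    out["corrected_p"] = np.maximum(corrected, out["raw_p"].to_numpy())
    return out


def filter_confounded(results: pd.DataFrame, alpha: float = 0.01) -> tuple[list, pd.DataFrame]:
    """Peaks retained after removing those significant for ANY factor.

    ``results`` concatenates corrected per-factor frames.  Returns the
    retained peak list (input order preserved) and a per-factor removal
    count table.
    """
    if "corrected_p" not in results:
        raise ValueError("results must carry corrected_p")
    sig = results[results["corrected_p"] < alpha]
    removed = set(sig["peak_id"])
    counts = (sig.groupby("factor")["peak_id"].nunique()
              .reindex(sorted(results["factor"].unique()), fill_value=0)
              .rename("n_removed").to_frame())
    order = results["peak_id"].drop_duplicates()
    retained = [p for p in order if p not in removed]
    return retained, counts


def confounder_scan(
    table: PeakTable,
    cohort: Cohort,
    factors=tuple(FACTOR_SPECS),
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.01,
) -> tuple[list, pd.DataFrame, pd.DataFrame]:
    """Run every factor test + correction and drop confounded peaks.

    Returns (retained peak ids, full results frame, removal counts).
    """
    ss = np.random.SeedSequence(seed)
    frames = []
    for factor, child in zip(factors, ss.spawn(len(factors))):
        frames.append(permutation_correct(table, cohort, factor, n_perm=n_perm,
                                          seed=child))
    results = pd.concat(frames, ignore_index=True)
    retained, counts = filter_confounded(results, alpha=alpha)
    return retained, results, counts


# ---------------------------------------------------------------------------
# age polynomial
# ---------------------------------------------------------------------------

def fit_age_polynomial(
    age, values, max_degree: int = 3, alpha: float = 0.01
) -> dict:
    """Test a peak for age dependence with a polynomial of degree <= 3.

    The degree (1..max_degree) is chosen by adjusted R² and the selected
    polynomial is tested against the constant model by F-test.  Returns
    {'is_age_related', 'best_degree', 'F', 'F_p', 'flagged'}.
    """
    age = np.asarray(age, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(age) & np.isfinite(y)
    age, y = age[ok], y[ok]
    n = len(y)
    if np.unique(age).size < max_degree + 2:
        return {"is_age_related": False, "best_degree": 0, "F": np.nan,
                "F_p": np.nan, "flagged": True}
    tss = ((y - y.mean()) ** 2).sum()
    best = None
    for d in range(1, max_degree + 1):
        coef = np.polyfit(age, y, d)
        rss = ((y - np.polyval(coef, age)) ** 2).sum()
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - d - 1)
        if best is None or adj > best[0]:
            best = (adj, d, rss)
    _, d, rss = best
    if rss <= 0:
        return {"is_age_related": True, "best_degree": d, "F": np.inf,
                "F_p": 0.0, "flagged": False}
    F = ((tss - rss) / d) / (rss / (n - d - 1))
    p = float(stats.f.sf(F, d, n - d - 1))
    return {"is_age_related": bool(p < alpha), "best_degree": int(d),
            "F": float(F), "F_p": p, "flagged": False}
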