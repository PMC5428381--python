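"""Characterization of the selected MLS-predictor lipids.

Covers: cross-clade concordance of concentration changes; lipid
class/sub-class/pathway enrichment (hypergeometric with an empirical
resampling family-wise correction); directional concentration-shift
tests within enriched groups; the double-bond/concentration-change
association; and predictor-set overlap between tissues.

"Change" for a peak and clade is the difference between the mean log
concentration in the long-living species of the clade and the mean in
all its other species.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import label_long_living
from .datatypes import Cohort, PeakTable


# ---------------------------------------------------------------------------
# per-clade concentration changes
# ---------------------------------------------------------------------------

def clade_changes(table: PeakTable, cohort: Cohort, peaks=None) -> pd.DataFrame:
    """Peak × clade matrix of long-minus-other mean log-concentration."""
    peaks = list(peaks) if peaks is not None else list(table.peak_ids)
    lab = label_long_living(cohort.species)
    samples = cohort.samples.loc[table.sample_ids]
    vals = table.values[peaks]
    out = {}
    for clade in sorted(lab["clade"].unique()):
        sp = lab.index[lab["clade"] == clade]
        mask = samples["species_id"].isin(sp).to_numpy()
        long_sp = lab.index[(lab["clade"] == clade) & lab["is_long_living"]]
        is_long = samples["species_id"].isin(long_sp).to_numpy()
        long_mean = vals[mask & is_long].mean(axis=0)
        other_mean = vals[mask & ~is_long].mean(axis=0)
        out[clade] = long_mean - other_mean
    return pd.DataFrame(out)


def crossclade_change_correlation(
    table: PeakTable, cohort: Cohort, predictor_peaks,
    n_perm: int = 1000, seed: int | None = None,
) -> pd.DataFrame:
    """Pearson correlation of predictor concentration changes per clade pair.

    The null permutes the peak identity of one clade's change vector;
    the one-sided (positive) permutation p uses the add-one estimator.
    """
    predictor_peaks = list(predictor_peaks)
    if len(predictor_peaks) < 3:
        raise ValueError("need >= 3 predictor peaks")
    ch = clade_changes(table, cohort, predictor_peaks)
    rng = np.random.default_rng(seed)
    clades = list(ch.columns)
    rows = []
    for i in range(len(clades)):
        for j in range(i + 1, len(clades)):
            a = ch[clades[i]].to_numpy()
            b = ch[clades[j]].to_numpy()
            r = float(np.corrcoef(a, b)[0, 1])
            null = np.empty(n_perm)
            for k in range(n_perm):
                null[k] = np.corrcoef(a, rng.permutation(b))[0, 1]
            p = float((1 + (null >= r).sum()) / (n_perm + 1))
            rows.append({"clade_a": clades[i], "clade_b": clades[j],
                         "r": r, "perm_p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def hypergeom_upper_p(overlap: int, universe: int, group: int, draws: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, group, draws)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, group, draws))


def peak_groups(peak_meta: pd.DataFrame, reference: pd.DataFrame,
                level: str) -> pd.Series:
    """Map peak id → group label (lipid_class / sub_class / pathway)."""
    comp = peak_meta["compound_id"]
    ann = comp[comp.astype(str) != ""]
    return reference.loc[ann, level].set_axis(ann.index)


def class_enrichment(
    predictor_peaks, groups: pd.Series, universe,
    n_samp: int = 1000, seed: int | None = None, alpha: float = 0.05,
) -> pd.DataFrame:
    """Group over-representation among predictors with empirical correction.

    ``groups`` maps annotated peak → group label; ``universe`` is the
    detected annotated peak set.  Per group the hypergeometric
    upper-tail p is computed; the empirical family-wise p compares it
    with the minimum group p over ``n_samp`` random predictor-sized
    draws from the universe (add-one estimator, floor 1/(n_samp+1)).
    """
    universe = pd.Index([p for p in universe if p in groups.index])
    if len(universe) == 0:
        raise ValueError("no annotated peaks in the universe")
    pred = [p for p in predictor_peaks if p in universe]
    n_draw = len(pred)
    glabels = groups.loc[universe]
    names = sorted(glabels.unique())
    sizes = glabels.value_counts()
    pred_labels = glabels.loc[pred]

    rows = []
    for g in names:
        k = int((pred_labels == g).sum())
        rows.append({"group_id": g, "overlap": k, "group_size": int(sizes[g]),
                     "universe": len(universe), "n_predictors": n_draw,
                     "hyper_p": hypergeom_upper_p(k, len(universe),
                                                  int(sizes[g]), n_draw)})
    res = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    codes = pd.Categorical(glabels, categories=names).codes
    n_groups = len(names)
    size_vec = np.array([sizes[g] for g in names])
    min_null = np.empty(n_samp)
    for b in range(n_samp):
        draw = rng.choice(codes, size=n_draw, replace=False)
        counts = np.bincount(draw, minlength=n_groups)
        ps = stats.hypergeom.sf(counts - 1, len(universe), size_vec, n_draw)
        min_null[b] = ps.min()
    res["perm_p"] = [(1 + (min_null <= p).sum()) / (n_samp + 1)
                     for p in res["hyper_p"]]
    res["significant"] = res["perm_p"] < alpha
    return res


# ---------------------------------------------------------------------------
# concentration shifts
# ---------------------------------------------------------------------------

def concentration_shift_test(
    group_peaks, changes: pd.DataFrame, predictor_peaks,
    n_perm: int = 1000, seed: int | None = None, alpha: float = 0.05,
) -> dict:
    """Directional shift of a lipid group's predictor changes.

    Statistic: median across clades of the median change of the group's
    peaks.  Null: equally sized peak sets resampled from all predictors.
    Two-sided permutation p; direction = sign of the statistic when
    significant, else 'none'.
    """
    group_peaks = [p for p in group_peaks if p in changes.index]
    if len(group_peaks) == 0:
        raise ValueError("group has no peaks with change values")
    pred = [p for p in predictor_peaks if p in changes.index]
    obs = float(changes.loc[group_peaks].median(axis=0).median())
    rng = np.random.default_rng(seed)
    k = len(group_peaks)
    arr = changes.loc[pred].to_numpy()
    null = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(len(pred), size=k, replace=False)
        null[b] = np.median(np.median(arr[idx], axis=0))
    center = float(np.median(null))
    p = float((1 + (np.abs(null - center) >= abs(obs - center)).sum()) / (n_perm + 1))
    direction = "none"
    if p < alpha:
        direction = "up" if obs > center else "down"
    return {"statistic": obs, "null_center": center, "p": p, "direction": direction}


# ---------------------------------------------------------------------------
# double bonds
# ---------------------------------------------------------------------------

def doublebond_association(
    group_peaks, double_bonds: pd.Series, changes: pd.DataFrame,
    n_perm: int = 1000, seed: int | None = None,
) -> dict:
    """Spearman association of double-bond count with concentration change.

    Change per peak is the median over clades.  Permutation p shuffles
    the double-bond counts (two-sided, add-one).  Also reports the
    median double-bond count with its 0.25–0.75 quartiles.
    """
    peaks = [p for p in group_peaks if p in changes.index and p in double_bonds.index]
    db = double_bonds.loc[peaks].to_numpy(dtype=float)
    med = np.quantile(db, (0.25, 0.5, 0.75)) if len(db) else (np.nan,) * 3
    if len(peaks) == 0 or np.unique(db).size < 2:
        return {"rho": np.nan, "p": 1.0, "defined": False,
                "median_db": float(med[1]) if len(db) else np.nan,
                "db_q25": float(med[0]) if len(db) else np.nan,
                "db_q75": float(med[2]) if len(db) else np.nan}
    ch = changes.loc[peaks].median(axis=1).to_numpy()
    rho = float(stats.spearmanr(db, ch).statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = stats.spearmanr(rng.permutation(db), ch).statistic
    p = float((1 + (np.abs(null) >= abs(rho)).sum()) / (n_perm + 1))
    return {"rho": rho, "p": p, "defined": True,
            "median_db": float(med[1]), "db_q25": float(med[0]),
            "db_q75": float(med[2])}


# ---------------------------------------------------------------------------
# tissue overlap
# ---------------------------------------------------------------------------

def tissue_overlap(set_a, set_b, universe) -> dict:
    """Hypergeometric overlap significance of two predictor sets within a
    matched peak universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty matched universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    k = len(a & b)
    p = hypergeom_upper_p(k, len(universe), len(a), len(b))
    return {"overlap": k, "n_a": len(a), "n_b": len(b),
            "universe": len(universe), "p": p}
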