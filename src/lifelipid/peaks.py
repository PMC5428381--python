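"""Peak-table processing: internal-standard normalization, QC, detection
filtering, adduct annotation against a lipid reference, redundant-peak
merging, and cross-dataset peak matching.

All concentration values downstream of :func:`normalize_by_internal_standard`
are natural-log ratios to the per-sample internal standard.
"""

from __future__ import annotations

from dataclasses import replace

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import Cohort, PeakTable


# ---------------------------------------------------------------------------
# normalization & QC
# ---------------------------------------------------------------------------

def normalize_by_internal_standard(
    table: PeakTable, is_peak: str
) -> tuple[PeakTable, list]:
    """Divide every intensity by the sample's internal-standard level and
    log transform.

    The IS peak is dropped from the output matrix.  Samples in which the
    IS was not detected cannot be normalized; they are removed and their
    ids returned as the second element.
    """
    if table.log_scale:
        raise ValueError("table is already on log scale")
    if is_peak not in table.peak_ids:
        raise KeyError(f"internal-standard peak {is_peak!r} not in table")
    is_vals = table.values[is_peak]
    is_det = table.detected[is_peak]
    flagged = list(table.sample_ids[~is_det | ~(is_vals > 0)])
    keep = table.sample_ids.difference(flagged, sort=False)

    other = table.peak_ids.drop(is_peak)
    vals = table.values.loc[keep, other]
    norm = np.log(vals.div(is_vals.loc[keep], axis=0))
    out = PeakTable(
        values=norm,
        detected=table.detected.loc[keep, other],
        peak_meta=table.peak_meta.loc[other],
        log_scale=True,
        tissue=table.tissue,
    )
    return out, flagged


def qc_filter_samples(is_levels: pd.Series, k_sd: float = 2.5) -> list:
    """Samples whose IS level lies within ``k_sd`` standard deviations of
    the tissue mean.

    Mean and SD are computed once, on all samples, before any removal
    (single pass).  Raises if every sample would be dropped.
    """
    if len(is_levels) < 3:
        raise ValueError("need at least 3 samples per tissue for IS QC")
    x = is_levels.astype(float)
    mean, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        return list(x.index)
    keep = x.index[(x - mean).abs() <= k_sd * sd]
    if len(keep) == 0:
        raise ValueError("IS QC removed every sample")
    return list(keep)


def detection_filter(table: PeakTable, cohort: Cohort, min_fraction: float = 0.5) -> list:
    """Peaks detected in >= ``min_fraction`` of individuals of at least one
    species (within this table's tissue)."""
    species = cohort.samples.loc[table.sample_ids, "species_id"].to_numpy()
    frac = table.detected.groupby(species).mean()
    keep = table.peak_ids[(frac >= min_fraction).any(axis=0)]
    return list(keep)


def impute_half_minimum(table: PeakTable) -> PeakTable:
    """Replace undetected log values by half the per-peak minimum detected
    value (log-scale: min − ln 2), a standard left-censoring surrogate."""
    if not table.log_scale:
        raise ValueError("imputation expects a log-scale table")
    fill = table.values.min(axis=0) - np.log(2.0)
    values = table.values.fillna(fill)
    return replace(table, values=values)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _parse_adducts(spec: str) -> list:
    out = []
    for item in str(spec).split(";"):
        if not item:
            continue
        name, shift, mode = item.rsplit(":", 2)
        out.append((name, float(shift), mode))
    return out


#: adduct names treated as the common ("primary") forms per mode
PRIMARY_ADDUCTS = {"[M+H]+", "[M-H]-"}


def annotate_adducts(
    table: PeakTable, reference: pd.DataFrame, tol_ppm: float = 10.0
) -> pd.DataFrame:
    """Match peaks to reference compounds through allowed adducts.

    A peak matches compound *c* via adduct *a* when the relative mass
    error ``|mz_obs − mz_exp| / mz_exp × 1e6`` is at most ``tol_ppm`` and
    *a* is allowed for the class of *c* in the peak's ionization mode.
    The common adducts are searched first, the rare ones in a second
    pass; all matches are kept, and peaks matching more than one
    compound are flagged ambiguous.

    Returns a DataFrame with columns peak_id, compound_id, adduct, mode,
    ppm, stage ('primary'/'rare'), ambiguous.
    """
    if len(reference) == 0:
        raise ValueError("empty reference table")
    meta = table.peak_meta
    peaks = meta.index[meta.index != ""]

    # expected m/z per (compound, adduct, mode)
    exp_rows = []
    for comp, ref in reference.iterrows():
        for name, shift, mode in _parse_adducts(ref["adducts"]):
            exp_rows.append((comp, name, mode,
                             float(ref["monoisotopic_mass"]) + shift,
                             "primary" if name in PRIMARY_ADDUCTS else "rare"))
    exp = pd.DataFrame(exp_rows,
                       columns=["compound_id", "adduct", "mode", "mz_exp", "stage"])

    matches = []
    for stage in ("primary", "rare"):
        sub = exp[exp["stage"] == stage]
        for mode in ("pos", "neg"):
            cand = sub[sub["mode"] == mode]
            if cand.empty:
                continue
            pk = meta[meta["mode"] == mode]
            if pk.empty:
                continue
            mz_obs = pk["mz"].to_numpy()[:, None]
            mz_exp = cand["mz_exp"].to_numpy()[None, :]
            ppm = np.abs(mz_obs - mz_exp) / mz_exp * 1e6
            ii, jj = np.nonzero(ppm <= tol_ppm)
            for i, j in zip(ii, jj):
                matches.append({
                    "peak_id": pk.index[i],
                    "compound_id": cand["compound_id"].iloc[j],
                    "adduct": cand["adduct"].iloc[j],
                    "mode": mode,
                    "ppm": float(ppm[i, j]),
                    "stage": stage,
                })
    ann = pd.DataFrame(matches,
                       columns=["peak_id", "compound_id", "adduct", "mode", "ppm", "stage"])
    if len(ann):
        n_comp = ann.groupby("peak_id")["compound_id"].nunique()
        ann["ambiguous"] = ann["peak_id"].map(n_comp > 1)
        ann = ann.sort_values(["peak_id", "stage", "ppm"],
                              key=lambda s: s.map({"primary": 0, "rare": 1})
                              if s.name == "stage" else s).reset_index(drop=True)
    else:
        ann["ambiguous"] = pd.Series(dtype=bool)
    return ann


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_peaks(
    table: PeakTable,
    annotations: pd.DataFrame,
    corr_min: float = 0.7,
    rt_max_diff: float = 0.05,
    min_shared: int = 3,
) -> tuple[PeakTable, pd.DataFrame]:
    """Merge redundant peaks of the same compound.

    Peaks are joined by an edge when (i) they matched the same compound,
    (ii) their retention times differ by less than ``rt_max_diff``
    minutes, and (iii) their Pearson correlation over jointly detected
    samples exceeds ``corr_min`` (undefined below ``min_shared`` shared
    samples → no edge).  Connected components become composite peaks
    whose per-sample value is the arithmetic mean of the member log
    concentrations; the composite keeps the id of its first member.

    Returns the merged table and a composite summary (composite_id,
    members, n_members).
    """
    if not table.log_scale:
        raise ValueError("merge_peaks expects a log-scale (normalized) table")
    meta = table.peak_meta
    vals = table.values
    det = table.detected

    g = nx.Graph()
    g.add_nodes_from(table.peak_ids)
    if len(annotations):
        by_comp = annotations.groupby("compound_id")["peak_id"].unique()
        for comp, members in by_comp.items():
            members = [p for p in members if p in vals.columns]
            for a_i in range(len(members)):
                for b_i in range(a_i + 1, len(members)):
                    a, b = members[a_i], members[b_i]
                    if g.has_edge(a, b):
                        continue
                    if abs(meta.at[a, "rt"] - meta.at[b, "rt"]) >= rt_max_diff:
                        continue
                    shared = (det[a] & det[b]).to_numpy()
                    if shared.sum() < min_shared:
                        continue
                    xa = vals[a].to_numpy()[shared]
                    xb = vals[b].to_numpy()[shared]
                    if xa.std() == 0 or xb.std() == 0:
                        continue
                    if np.corrcoef(xa, xb)[0, 1] > corr_min:
                        g.add_edge(a, b)

    order = {p: i for i, p in enumerate(table.peak_ids)}
    new_vals, new_det, meta_rows, comp_rows = {}, {}, [], []
    for comp_nodes in nx.connected_components(g):
        members = sorted(comp_nodes, key=order.get)
        cid = members[0]
        if len(members) == 1:
            new_vals[cid] = vals[cid]
            new_det[cid] = det[cid]
        else:
            block = vals[members]
            new_vals[cid] = block.mean(axis=1, skipna=True)
            new_det[cid] = det[members].any(axis=1)
        row = meta.loc[cid].to_dict()
        row["n_members"] = len(members)
        row["members"] = ";".join(members)
        meta_rows.append((cid, row))
        comp_rows.append({"composite_id": cid, "members": ";".join(members),
                          "n_members": len(members)})

    meta_rows.sort(key=lambda kv: order[kv[0]])
    cols = [cid for cid, _ in meta_rows]
    merged_meta = pd.DataFrame({cid: row for cid, row in meta_rows}).T.loc[cols]
    merged_meta.index.name = "peak_id"
    for col in ("mz", "rt"):
        merged_meta[col] = merged_meta[col].astype(float)
    merged = PeakTable(
        values=pd.DataFrame(new_vals)[cols],
        detected=pd.DataFrame(new_det)[cols],
        peak_meta=merged_meta,
        log_scale=True,
        tissue=table.tissue,
    )
    composites = pd.DataFrame(comp_rows).set_index("composite_id")
    composites = composites.loc[[c for c in cols]]
    return merged, composites


# ---------------------------------------------------------------------------
# cross-dataset matching
# ---------------------------------------------------------------------------

def match_across_datasets(
    meta_a: pd.DataFrame,
    meta_b: pd.DataFrame,
    tol_ppm: float = 10.0,
    rt_tol_sec: float = 0.1,
) -> pd.DataFrame:
    """One-to-one peak matching between two datasets by m/z and RT.

    Candidate pairs must agree in ionization mode, lie within
    ``tol_ppm`` relative mass difference and within ``rt_tol_sec``
    seconds of retention time (RT metadata is in minutes).  Candidates
    are resolved one-to-one greedily by nearest m/z, ties broken by
    nearest RT then by lower peak index in the second table.
    """
    rows = []
    b_order = {p: i for i, p in enumerate(meta_b.index)}
    for mode in ("pos", "neg"):
        a = meta_a[meta_a["mode"] == mode]
        b = meta_b[meta_b["mode"] == mode]
        if a.empty or b.empty:
            continue
        mza = a["mz"].to_numpy()[:, None]
        mzb = b["mz"].to_numpy()[None, :]
        ppm = np.abs(mza - mzb) / mzb * 1e6
        drt = np.abs(a["rt"].to_numpy()[:, None] - b["rt"].to_numpy()[None, :]) * 60.0
        ii, jj = np.nonzero((ppm <= tol_ppm) & (drt <= rt_tol_sec))
        for i, j in zip(ii, jj):
            rows.append((a.index[i], b.index[j], float(ppm[i, j]),
                         float(drt[i, j]), b_order[b.index[j]]))
    cand = pd.DataFrame(rows, columns=["peak_a", "peak_b", "ppm", "drt_sec", "b_idx"])
    cand = cand.sort_values(["ppm", "drt_sec", "b_idx"], kind="mergesort")
    used_a, used_b, keep = set(), set(), []
    for row in cand.itertuples(index=False):
        if row.peak_a in used_a or row.peak_b in used_b:
            continue
        used_a.add(row.peak_a)
        used_b.add(row.peak_b)
        keep.append(row)
    out = pd.DataFrame(keep, columns=["peak_a", "peak_b", "ppm", "drt_sec", "b_idx"])
    return out.drop(columns="b_idx").reset_index(drop=True)
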