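"""End-to-end pipeline: simulate → process → confounder-filter → fit →
holdout → characterize → enzyme evolution, with hierarchical seeding and
a machine-readable report.

Every stochastic stage receives a sub-seed derived from the run seed, so
individual stages can be re-run in isolation and two runs with the same
config are identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import characterize as ch
from . import classifiers as cl
from . import confounders as cf
from . import enzymes as ez
from . import holdout as ho
from . import peaks as pk
from . import simulate as sim
from .datatypes import TISSUES, as_json_safe

ALL_STAGES = ("simulate", "process", "confound", "fit", "holdout",
              "characterize", "evolve")


@dataclass
class RunConfig:
    """All thresholds and sizes of a pipeline run (defaults = study values)."""

    seed: int = 0
    stages: tuple = ALL_STAGES
    # simulate
    n_peaks: int = 300
    n_predictors: int = 20
    n_confounded_per_factor: int = 4
    effect_size: float = 2.0
    noise_sd: float = 0.5
    species_sd: float = 0.25
    missing_rate: float = 0.10
    n_individuals: int = 3
    n_enzymes: int = 908
    enzyme_effect: float = 0.5
    tissues: tuple = TISSUES
    # process
    tol_ppm: float = 10.0
    corr_min: float = 0.7
    rt_max_diff: float = 0.05
    rt_tol_sec: float = 0.1
    qc_k_sd: float = 2.5
    # confound
    confound_alpha: float = 0.01
    n_perm: int = 1000
    # fit
    alpha_grid: tuple = cl.DEFAULT_ALPHA_GRID
    lam_grid: tuple = cl.DEFAULT_LAM_GRID
    cv_folds: int = 10
    cv_repeats: int = 10
    # holdout
    holdout_clade: str = "primate"
    holdout_fractions: tuple = ho.DEFAULT_FRACTIONS
    holdout_reps: int = 100
    baseline_n_rand: int = 100
    # characterize / evolve
    n_samp: int = 1000
    enrich_alpha: float = 0.05

    def sub_seed(self, stage: str) -> int:
        idx = ALL_STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0]
                   % (2**31))


def _truth_recovery(selected, truth, composites) -> float:
    """Fraction of planted predictor peaks recovered, composite-aware."""
    member_map = {}
    for cid, row in composites.iterrows():
        for m in str(row["members"]).split(";"):
            member_map[m] = cid
    hit = 0
    sel = set(selected)
    for p in truth.predictor_peaks:
        if member_map.get(p, p) in sel:
            hit += 1
    return hit / max(1, len(truth.predictor_peaks))


def run_pipeline(config: RunConfig, out_dir=None, return_state: bool = False):
    """Execute the enabled stages in order and return the run report.

    With ``return_state`` the intermediate objects (cohort, tables,
    truth, fitted results) are returned alongside the report.
    """
    report: dict = {"config": asdict(config), "stages": {}, "timing_sec": {}}
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](config, state, report)
        except Exception as err:  # pragma: no cover - error path
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        report["timing_sec"][stage] = round(time.time() - t0, 3)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(as_json_safe(report), indent=2))
    if return_state:
        return report, state
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, state: dict, report: dict) -> None:
    seed = config.sub_seed("simulate")
    cohort = sim.generate_cohort(n_individuals=config.n_individuals,
                                 tissues=config.tissues, seed=seed)
    tables, reference, truth = sim.generate_lipidome(
        cohort, n_peaks=config.n_peaks, n_predictors=config.n_predictors,
        n_confounded_per_factor=config.n_confounded_per_factor,
        effect_size=config.effect_size, noise_sd=config.noise_sd,
        species_sd=config.species_sd, missing_rate=config.missing_rate,
        seed=seed + 1)
    enzymes, truth = sim.generate_enzyme_tables(
        truth, reference, n_enzymes=config.n_enzymes,
        enzyme_effect=config.enzyme_effect, seed=seed + 2)
    state.update(cohort=cohort, tables=tables, reference=reference,
                 truth=truth, enzymes=enzymes)
    report["stages"]["simulate"] = {
        "seed": seed,
        "n_species": cohort.n_species,
        "n_clades": cohort.species["clade"].nunique(),
        "n_samples": cohort.n_samples,
        "n_tissues": len(config.tissues),
        "n_peaks": config.n_peaks,
        "n_long_living": int(cl.label_long_living(cohort.species)
                             ["is_long_living"].sum()),
    }


def _stage_process(config: RunConfig, state: dict, report: dict) -> None:
    cohort = state["cohort"]
    processed, annots, composites, info = {}, {}, {}, {}
    for tissue, raw in state["tables"].items():
        is_levels = raw.values[sim.IS_PEAK_ID]
        keep = pk.qc_filter_samples(is_levels.dropna(), k_sd=config.qc_k_sd)
        raw_q = raw.subset_samples(keep)
        norm, dropped = pk.normalize_by_internal_standard(raw_q, sim.IS_PEAK_ID)
        kept_peaks = pk.detection_filter(norm, cohort)
        norm = norm.subset_peaks(kept_peaks)
        ann = pk.annotate_adducts(norm, state["reference"], tol_ppm=config.tol_ppm)
        merged, comp = pk.merge_peaks(norm, ann, corr_min=config.corr_min,
                                      rt_max_diff=config.rt_max_diff)
        merged = pk.impute_half_minimum(merged)
        processed[tissue] = merged
        annots[tissue] = ann
        composites[tissue] = comp
        info[tissue] = {
            "n_samples": merged.n_samples,
            "qc_removed": raw.n_samples - len(keep),
            "is_missing_removed": len(dropped),
            "detection_kept": len(kept_peaks),
            "n_annotated_peaks": int(ann["peak_id"].nunique()) if len(ann) else 0,
            "n_merged_composites": int((comp["n_members"] > 1).sum()),
            "n_peaks_final": merged.n_peaks,
        }
    state.update(processed=processed, annotations=annots, composites=composites)
    report["stages"]["process"] = info


def _stage_confound(config: RunConfig, state: dict, report: dict) -> None:
    seed = config.sub_seed("confound")
    cohort = state["cohort"]
    filtered, info = {}, {}
    for k, (tissue, table) in enumerate(state["processed"].items()):
        retained, results, counts = cf.confounder_scan(
            table, cohort, n_perm=config.n_perm, seed=seed + k,
            alpha=config.confound_alpha)
        filtered[tissue] = table.subset_peaks(retained)
        info[tissue] = {
            "n_retained": len(retained),
            "n_removed": table.n_peaks - len(retained),
            "removed_per_factor": counts["n_removed"].to_dict(),
        }
    state["filtered"] = filtered
    report["stages"]["confound"] = info


def _stage_fit(config: RunConfig, state: dict, report: dict) -> None:
    seed = config.sub_seed("fit")
    cohort = state["cohort"]
    truth = state.get("truth")
    results, info = {}, {}
    for k, (tissue, table) in enumerate(state["filtered"].items()):
        model = cl.LongevityClassifier.from_table(table, cohort)
        res = model.fit_cv(alpha_grid=config.alpha_grid, lam_grid=config.lam_grid,
                           folds=config.cv_folds, repeats=config.cv_repeats,
                           seed=seed + k)
        results[tissue] = res
        entry = {
            "cv_auc": res.cv_auc,
            "best_alpha": res.model.alpha,
            "best_lam": res.model.lam,
            "n_predictors": len(res.selected_peaks),
            "predictor_fraction": res.predictor_fraction,
        }
        if truth is not None:
            entry["truth_recovery"] = _truth_recovery(
                res.selected_peaks, truth, state["composites"][tissue])
        info[tissue] = entry
    state["fit_results"] = results
    aucs = [v["cv_auc"] for v in info.values()]
    report["stages"]["fit"] = {
        "per_tissue": info,
        "mean_auc": float(np.mean(aucs)),
        "max_auc": float(np.max(aucs)),
    }


def _stage_holdout(config: RunConfig, state: dict, report: dict) -> None:
    seed = config.sub_seed("holdout")
    cohort = state["cohort"]
    # fixed penalty parameters: the CV choice of the largest tissue dataset
    some = next(iter(state["fit_results"].values()))
    res = ho.run_clade_elimination(
        state["filtered"], cohort, clade=config.holdout_clade,
        fractions=config.holdout_fractions, reps=config.holdout_reps,
        alpha=some.model.alpha, lam=some.model.lam, seed=seed)
    summary = ho.summarize_elimination(res)
    state["holdout_results"] = res
    report["stages"]["holdout"] = {
        "clade": config.holdout_clade,
        "summary": summary.to_dict(orient="records"),
    }


def _stage_characterize(config: RunConfig, state: dict, report: dict) -> None:
    seed = config.sub_seed("characterize")
    cohort = state["cohort"]
    reference = state["reference"]
    info = {}
    predictor_sets = {t: set(r.selected_peaks)
                      for t, r in state["fit_results"].items()}
    for k, (tissue, table) in enumerate(state["filtered"].items()):
        pred = sorted(predictor_sets[tissue])
        entry = {}
        if len(pred) >= 3:
            corr = ch.crossclade_change_correlation(
                table, cohort, pred, n_perm=config.n_samp, seed=seed + 3 * k)
            entry["crossclade"] = corr.to_dict(orient="records")
        groups = ch.peak_groups(table.peak_meta, reference, "sub_class")
        universe = [p for p in table.peak_ids if p in groups.index]
        pred_ann = [p for p in pred if p in groups.index]
        if pred_ann and universe:
            enr = ch.class_enrichment(pred_ann, groups, universe,
                                      n_samp=config.n_samp, seed=seed + 3 * k + 1,
                                      alpha=config.enrich_alpha)
            changes = ch.clade_changes(table, cohort, pred_ann)
            shifts = {}
            for g in enr.loc[enr["significant"], "group_id"]:
                gp = [p for p in pred_ann if groups.get(p) == g]
                if gp:
                    shifts[g] = ch.concentration_shift_test(
                        gp, changes, pred_ann, n_perm=config.n_samp,
                        seed=seed + 3 * k + 2)
            entry["enrichment"] = enr.to_dict(orient="records")
            entry["shifts"] = shifts
        info[tissue] = entry
    # tissue overlap on the shared peak panel
    tissues = list(state["filtered"])
    overlaps = []
    for i in range(len(tissues)):
        for j in range(i + 1, len(tissues)):
            ta, tb = tissues[i], tissues[j]
            pairs = pk.match_across_datasets(
                state["filtered"][ta].peak_meta, state["filtered"][tb].peak_meta,
                tol_ppm=config.tol_ppm, rt_tol_sec=config.rt_tol_sec)
            matched_a = set(pairs["peak_a"])
            b_of_a = dict(zip(pairs["peak_a"], pairs["peak_b"]))
            set_a = predictor_sets[ta] & matched_a
            set_b = {p for p in matched_a
                     if b_of_a[p] in predictor_sets[tb]}
            if matched_a:
                ov = ch.tissue_overlap(set_a, set_b, matched_a)
                ov.update(tissue_a=ta, tissue_b=tb)
                overlaps.append(ov)
    report["stages"]["characterize"] = {"per_tissue": info,
                                        "tissue_overlap": overlaps}
    state["predictor_sets"] = predictor_sets


def _stage_evolve(config: RunConfig, state: dict, report: dict) -> None:
    enzymes = state["enzymes"]
    reference = state["reference"]
    info = {}
    for tissue, table in state["filtered"].items():
        pred = state["predictor_sets"].get(tissue, set()) if "predictor_sets" in state \
            else set()
        if not pred:
            continue
        meta = table.peak_meta
        comp = meta.loc[[p for p in pred if p in meta.index], "compound_id"]
        pred_compounds = sorted(set(c for c in comp if c))
        if not pred_compounds:
            continue
        selected = ez.select_lifespan_enzymes(enzymes, pred_compounds,
                                              tissue=tissue)
        entry = {"n_selected": len(selected),
                 "q": ez.tissue_quantile(tissue)}
        for branch in ("long", "short"):
            entry[f"dnds_{branch}"] = ez.compare_dnds(enzymes, selected,
                                                      branch=branch)
        res, g = ez.term_enrichment_network(enzymes, selected)
        entry["n_significant_terms"] = int(res["significant"].sum())
        entry["n_network_edges"] = g.number_of_edges()
        info[tissue] = entry
    report["stages"]["evolve"] = info


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "process": _stage_process,
    "confound": _stage_confound,
    "fit": _stage_fit,
    "holdout": _stage_holdout,
    "characterize": _stage_characterize,
    "evolve": _stage_evolve,
}
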