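"""Synthetic cohort, lipidome and enzyme-evolution generator.

Emulates the statistical structure of a comparative tissue-lipidomics
study of mammalian maximal lifespan (MLS): three clades (rodents,
primates, bats) with 1–2 exceptionally long-living species each, six
tissues, untargeted peak tables on both ionization modes, an internal
standard spiked into every sample, confounder-driven lipids, and a table
of lipid-linked enzymes with per-branch dN/dS values.

Every downstream stage has a planted ground truth here, so the whole
pipeline can be exercised with known answers:

* *predictor peaks* carry a concentration shift in long-living species
  with the same sign in all three clades;
* *confounded peaks* are linear functions of one non-MLS factor
  (sex, hibernation, diet, BMR, body temperature, body mass or age);
* a subset of enzymes is preferentially linked to predictor compounds
  and receives a reduced dN/dS on the long-living branch only.

All draws flow through a single :func:`numpy.random.default_rng` stream,
so identical ``(config, seed)`` gives bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CLADES, TISSUES, Cohort, PeakTable

# ---------------------------------------------------------------------------
# defaults: the study conditions
# ---------------------------------------------------------------------------

#: species per clade (sums to 35)
DEFAULT_SPECIES_PER_CLADE = {"rodent": 16, "primate": 12, "bat": 7}
#: MLS range (years) per clade
DEFAULT_MLS_RANGES = {"rodent": (4.0, 31.0), "primate": (15.0, 100.0), "bat": (10.0, 33.0)}
#: long-living species per clade (naked mole-rat; human; two bat species)
DEFAULT_N_LONG = {"rodent": 1, "primate": 1, "bat": 2}
DEFAULT_N_INDIVIDUALS = 3

#: per-tissue multiplier on the planted effect; cortex is the designated
#: high-signal tissue (the brain signal is the most clade-conserved one)
DEFAULT_TISSUE_EFFECT = {
    "liver": 1.0, "muscle": 1.0, "kidney": 1.0,
    "heart": 1.0, "cortex": 1.5, "cerebellum": 1.2,
}

CONFOUNDER_FACTORS = ("sex", "hibernation", "diet", "bmr", "body_temp", "body_mass", "age")

#: internal standard: PC 34:0, spiked into every sample
IS_PEAK_ID = "IS_PC34_0"
IS_MASS = 733.5622  # monoisotopic mass of PC 34:0, Da
IS_CENTER = 1.0e5   # nominal IS intensity (arbitrary units)

ADDUCTS = {
    "pos": (
        ("[M+H]+", 1.007276, "primary"),
        ("[M+NH4]+", 18.033823, "rare"),
        ("[M+Na]+", 22.989218, "rare"),
    ),
    "neg": (
        ("[M-H]-", -1.007276, "primary"),
        ("[M+HCOO]-", 44.998201, "rare"),
        ("[M+Cl]-", 34.969402, "rare"),
    ),
}

# (class, sub-classes, pathway); pathways deliberately overlap across classes
CLASS_TABLE = (
    ("Sphingolipids", ("Ceramides", "Simple Glc series", "N-acylsphinganines"),
     "Sphingolipid metabolism"),
    ("Glycerolipids", ("Triacylglycerols", "Diacylglycerols"),
     "Glycerolipid metabolism"),
    ("Glycerophospholipids",
     ("Diacylglycerophosphocholines", "Diacylglycerophosphoethanolamines",
      "Diacylglycerophosphoinositols"),
     "Glycerophospholipid metabolism"),
    ("Fatty Acyls", ("Fatty acids", "Prostaglandins", "Eicosanoids"),
     "Fatty acid biosynthesis"),
    ("Sterol Lipids", ("Cholesteryl esters", "Bile acids"),
     "Steroid biosynthesis"),
    ("Prenol Lipids", ("Isoprenoids", "Quinones"),
     "Terpenoid backbone biosynthesis"),
)

EXTRA_PATHWAYS = (
    "Arachidonic acid metabolism", "Ether lipid metabolism",
    "Linoleic acid metabolism", "Glycosphingolipid biosynthesis",
    "Phosphatidylinositol signaling", "Fatty acid elongation",
)

DIETS = {
    "rodent": ("herbivore", "omnivore"),
    "primate": ("omnivore", "frugivore", "herbivore"),
    "bat": ("insectivore", "frugivore"),
}


@dataclass
class GroundTruth:
    """Planted truth for parameter-recovery tests."""

    predictor_peaks: tuple = ()
    predictor_signs: dict = field(default_factory=dict)
    predictor_compounds: tuple = ()
    confounded_peaks: dict = field(default_factory=dict)  # peak id -> factor
    effect_size: float = 0.0
    tissue_effect: dict = field(default_factory=dict)
    enzyme_effect: float = 0.0
    lifespan_enzymes: tuple = ()

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(
    n_species_per_clade: dict | None = None,
    n_individuals: int = DEFAULT_N_INDIVIDUALS,
    tissues=TISSUES,
    seed: int = 0,
    mls_ranges: dict | None = None,
    n_long: dict | None = None,
) -> Cohort:
    """Simulate the species table and individual samples.

    MLS is drawn per clade inside the configured range with the top 1–2
    species placed above the 0.9 × clade-max longevity cutoff by
    construction.  BMR follows an allometric power of body mass with
    lognormal scatter; diets and hibernation are clade-appropriate.
    """
    n_species_per_clade = dict(n_species_per_clade or DEFAULT_SPECIES_PER_CLADE)
    mls_ranges = dict(mls_ranges or DEFAULT_MLS_RANGES)
    n_long = dict(n_long or DEFAULT_N_LONG)
    tissues = tuple(tissues)
    if not tissues:
        raise ValueError("tissue list must be nonempty")
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    for clade, n in n_species_per_clade.items():
        if n < 2:
            raise ValueError(f"clade {clade!r} needs >= 2 species (got {n})")
        if n_long.get(clade, 1) >= n:
            raise ValueError(f"clade {clade!r}: long-living count must be < species count")

    rng = np.random.default_rng(seed)
    mass_logmean = {"rodent": np.log(250.0), "primate": np.log(5000.0), "bat": np.log(30.0)}

    rows = []
    for clade in sorted(n_species_per_clade):
        n = n_species_per_clade[clade]
        lo, hi = mls_ranges[clade]
        k_long = n_long.get(clade, 1)
        # clade maximum sits exactly at hi; further long-living species in
        # (0.93, 0.99)·hi (> 0.9·hi); the rest below 0.85·hi
        mls = np.empty(n)
        mls[0] = hi
        if k_long > 1:
            mls[1:k_long] = hi * rng.uniform(0.93, 0.99, size=k_long - 1)
        mls[k_long:] = rng.uniform(lo, 0.85 * hi, size=n - k_long)
        mass = np.exp(rng.normal(mass_logmean.get(clade, np.log(500.0)), 0.9, size=n))
        bmr = 3.4 * (mass / 1000.0) ** 0.75 * np.exp(rng.normal(0.0, 0.15, size=n))
        hib_p = {"rodent": 0.2, "primate": 0.0, "bat": 0.5}.get(clade, 0.1)
        for i in range(n):
            rows.append({
                "species_id": f"{clade}_{i:02d}",
                "clade": clade,
                "mls": float(mls[i]),
                "bmr": float(bmr[i]),
                "body_mass": float(mass[i]),
                "body_temp": float(rng.normal(36.5, 1.0)),
                "diet": str(rng.choice(DIETS.get(clade, ("omnivore",)))),
                "hibernates": bool(rng.random() < hib_p),
            })
    species = pd.DataFrame(rows).set_index("species_id")

    srows = []
    for sp, srec in species.iterrows():
        for i in range(n_individuals):
            ind = f"{sp}_i{i}"
            sex = "M" if rng.random() < 0.5 else "F"
            age = float(rng.uniform(0.05, 0.9) * srec["mls"])
            for tissue in tissues:
                srows.append({
                    "sample_id": f"{ind}_{tissue}",
                    "individual_id": ind,
                    "species_id": sp,
                    "tissue": tissue,
                    "sex": sex,
                    "age": age,
                    "is_level": float(np.exp(rng.normal(np.log(IS_CENTER), 0.25))),
                })
    samples = pd.DataFrame(srows).set_index("sample_id")
    return Cohort(species=species, samples=samples, tissues=tissues)


# ---------------------------------------------------------------------------
# lipid reference
# ---------------------------------------------------------------------------

def generate_reference(n_compounds: int, rng=None, seed: int = 0) -> pd.DataFrame:
    """Synthetic lipid-compound reference table (stand-in for a curated DB).

    Columns: monoisotopic_mass, lipid_class, sub_class, pathway,
    n_double_bonds, adducts (semicolon list of name:shift:mode).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    all_pathways = tuple(c[2] for c in CLASS_TABLE) + EXTRA_PATHWAYS
    rows = []
    for i in range(n_compounds):
        cls, subs, pathway = CLASS_TABLE[int(rng.integers(len(CLASS_TABLE)))]
        sub = str(rng.choice(subs))
        if rng.random() < 0.25:  # pathways are not 1:1 with classes
            pathway = str(rng.choice(all_pathways))
        db = int(min(rng.poisson(3), 12))
        if sub == "Fatty acids" and rng.random() < 0.4:
            db = 0  # saturated fatty acids
        adducts = ";".join(
            f"{name}:{shift:.6f}:{mode}"
            for mode in ("pos", "neg") for name, shift, _ in ADDUCTS[mode]
        )
        rows.append({
            "compound_id": f"C{i:04d}",
            "monoisotopic_mass": float(rng.uniform(250.0, 1200.0)),
            "lipid_class": cls,
            "sub_class": sub,
            "pathway": pathway,
            "n_double_bonds": db,
            "adducts": adducts,
            "rt_latent": float(rng.uniform(0.5, 19.5)),
        })
    return pd.DataFrame(rows).set_index("compound_id")


# ---------------------------------------------------------------------------
# lipidome
# ---------------------------------------------------------------------------

def _standardized(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def generate_lipidome(
    cohort: Cohort,
    n_peaks: int = 300,
    reference: pd.DataFrame | None = None,
    n_predictors: int = 20,
    n_confounded_per_factor: int = 4,
    effect_size: float = 2.0,
    tissue_effect: dict | None = None,
    noise_sd: float = 0.5,
    species_sd: float = 0.25,
    confounder_beta: float = 1.0,
    missing_rate: float = 0.10,
    n_duplicate_pairs: int = 12,
    annotated_fraction: float = 0.6,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame, GroundTruth]:
    """Simulate per-tissue raw peak tables with planted signal.

    Log-scale model per peak *j*, sample *i* (species *s*, tissue *t*)::

        log x_ij = mu_j + u_sj + d_j * effect_size * m_t * noise_sd * long(s)
                   + beta_f * z_f(i) * noise_sd [confounded peaks]
                   + eps_ij,   u ~ N(0, species_sd²), eps ~ N(0, noise_sd²)

    ``d_j`` is the planted sign, identical in all clades; ``m_t`` the
    per-tissue effect multiplier.  The raw table is the exponential of
    the log signal times the per-sample internal-standard factor, so the
    normalization stage's ``log(x / IS)`` round-trips the model.

    Returns ``(tables, reference, truth)`` where ``tables`` maps tissue
    name to a raw-scale :class:`PeakTable` (IS peak included).
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    if cohort.n_samples == 0:
        raise ValueError("cohort is empty")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    tissue_effect = dict(tissue_effect or DEFAULT_TISSUE_EFFECT)

    rng = np.random.default_rng(seed)

    n_base = n_peaks - 1 - n_duplicate_pairs  # minus IS, minus duplicate extras
    n_annot = int(round(annotated_fraction * n_base))
    if n_base < 1 or n_annot < max(n_predictors, 1):
        raise ValueError("n_peaks too small for the planted sets")
    if n_annot < n_duplicate_pairs:
        raise ValueError("n_duplicate_pairs exceeds the annotated peak count")
    n_conf = n_confounded_per_factor * len(CONFOUNDER_FACTORS)
    if n_predictors + n_conf > n_base:
        raise ValueError("planted sets exceed the number of peaks")

    if reference is None:
        reference = generate_reference(max(n_annot + 20, 120), rng=rng)
    if n_annot > len(reference):
        raise ValueError("reference table smaller than the annotated peak count")

    # ---- peak metadata ------------------------------------------------
    peak_ids = [f"P{i:04d}" for i in range(n_base + n_duplicate_pairs)]
    meta_rows = [{"peak_id": IS_PEAK_ID, "mz": IS_MASS + 1.007276, "rt": 9.0,
                  "mode": "pos", "compound_id": ""}]
    compounds = rng.choice(reference.index.to_numpy(), size=n_annot, replace=False)

    def _peak_row(pid, comp, jitter_rt=0.0):
        ref = reference.loc[comp]
        mode = "pos" if rng.random() < 0.5 else "neg"
        primary = rng.random() < 0.85
        cands = [a for a in ADDUCTS[mode] if (a[2] == "primary") == primary]
        name, shift, _ = cands[int(rng.integers(len(cands)))]
        eps = np.clip(rng.normal(0.0, 2e-6), -6e-6, 6e-6)
        return {
            "peak_id": pid,
            "mz": float((ref["monoisotopic_mass"] + shift) * (1.0 + eps)),
            "rt": float(np.clip(ref["rt_latent"] + jitter_rt, 0.0, 20.0)),
            "mode": mode,
            "compound_id": comp,
        }

    for k in range(n_annot):
        meta_rows.append(_peak_row(peak_ids[k], compounds[k]))
    for k in range(n_annot, n_base):
        meta_rows.append({
            "peak_id": peak_ids[k],
            "mz": float(rng.uniform(100.0, 1500.0)),
            "rt": float(rng.uniform(0.2, 19.8)),
            "mode": "pos" if rng.random() < 0.5 else "neg",
            "compound_id": "",
        })
    # duplicate peaks: same compound as an early annotated peak, RT within
    # the merge window, near-identical signal -> exercises merge_peaks
    dup_of = {}
    for k in range(n_duplicate_pairs):
        pid = peak_ids[n_base + k]
        dup_of[pid] = peak_ids[k]
        meta_rows.append(_peak_row(pid, compounds[k],
                                   jitter_rt=float(rng.uniform(-0.02, 0.02))))
        meta_rows[-1]["rt"] = float(np.clip(
            meta_rows[1 + k]["rt"] + rng.uniform(-0.02, 0.02), 0.0, 20.0))
    peak_meta = pd.DataFrame(meta_rows).set_index("peak_id")

    # ---- planted sets -------------------------------------------------
    annot_ids = np.array(peak_ids[:n_annot])
    cls = reference.loc[peak_meta.loc[annot_ids, "compound_id"], "lipid_class"].to_numpy()
    target = annot_ids[np.isin(cls, ["Sphingolipids", "Glycerolipids"])]
    other = annot_ids[~np.isin(cls, ["Sphingolipids", "Glycerolipids"])]
    n_target = min(len(target), int(round(0.7 * n_predictors)))
    pred = list(rng.choice(target, size=n_target, replace=False)) if n_target else []
    pool = np.setdiff1d(np.concatenate([target, other]), pred)
    pred += list(rng.choice(pool, size=n_predictors - len(pred), replace=False))
    pred = sorted(pred)

    signs = {}
    for pid in pred:
        c = reference.loc[peak_meta.loc[pid, "compound_id"], "lipid_class"]
        if c == "Sphingolipids":
            signs[pid] = -1.0  # sphingolipids shift down in long-living species
        elif c == "Glycerolipids":
            signs[pid] = +1.0  # triacylglycerols shift up
        else:
            signs[pid] = float(rng.choice([-1.0, 1.0]))

    remaining = np.setdiff1d(np.array(peak_ids[:n_base]), pred)
    conf_ids = rng.choice(remaining, size=n_conf, replace=False)
    confounded = {
        pid: CONFOUNDER_FACTORS[k // n_confounded_per_factor]
        for k, pid in enumerate(conf_ids)
    }

    truth = GroundTruth(
        predictor_peaks=tuple(pred),
        predictor_signs=signs,
        predictor_compounds=tuple(sorted(set(peak_meta.loc[pred, "compound_id"]))),
        confounded_peaks=dict(sorted(confounded.items())),
        effect_size=float(effect_size),
        tissue_effect=tissue_effect,
    )

    # ---- signal -------------------------------------------------------
    all_ids = [IS_PEAK_ID] + peak_ids
    mu = rng.uniform(11.0, 16.0, size=len(peak_ids))
    species_list = cohort.species.index.to_numpy()
    long_flag = _long_living_flags(cohort.species)

    # standardized confounder covariates
    sp = cohort.species
    z_species = {
        "hibernation": _standardized(sp["hibernates"].astype(float).to_numpy()),
        "bmr": _standardized(np.log(sp["bmr"].to_numpy())),
        "body_temp": _standardized(sp["body_temp"].to_numpy()),
        "body_mass": _standardized(np.log(sp["body_mass"].to_numpy())),
    }
    diet_codes = pd.Categorical(sp["diet"]).codes.astype(float)
    z_species["diet"] = _standardized(diet_codes)

    tables = {}
    pred_idx = np.array([peak_ids.index(p) for p in pred])
    sign_vec = np.array([signs[p] for p in pred])

    for tissue in cohort.tissues:
        smeta = cohort.samples_for_tissue(tissue)
        sample_ids = smeta.index
        n_s = len(sample_ids)
        sp_idx = pd.Index(species_list).get_indexer(smeta["species_id"])

        logv = np.tile(mu, (n_s, 1))
        u = rng.normal(0.0, species_sd, size=(len(species_list), len(peak_ids)))
        logv += u[sp_idx]
        # planted long-living shift, same sign in every clade
        shift = effect_size * tissue_effect.get(tissue, 1.0) * noise_sd
        logv[:, pred_idx] += np.outer(long_flag[sp_idx], sign_vec * shift)
        # confounder terms
        z_sex = _standardized((smeta["sex"] == "M").astype(float).to_numpy())
        z_age = _standardized(smeta["age"].to_numpy())
        for pid, factor in confounded.items():
            j = peak_ids.index(pid)
            if factor == "sex":
                z = z_sex
            elif factor == "age":
                z = z_age
            else:
                z = z_species[factor][sp_idx]
            logv[:, j] += confounder_beta * noise_sd * z
        logv += rng.normal(0.0, noise_sd, size=logv.shape)
        # duplicate peaks copy their base peak plus tiny noise
        for dpid, bpid in dup_of.items():
            jd, jb = peak_ids.index(dpid), peak_ids.index(bpid)
            logv[:, jd] = logv[:, jb] + rng.normal(0.0, 0.05, size=n_s)

        is_level = smeta["is_level"].to_numpy()
        raw = np.exp(logv) * (is_level / IS_CENTER)[:, None]
        raw = np.column_stack([is_level, raw])

        det = rng.random(size=raw.shape) >= missing_rate
        det[:, 0] = True  # IS always detected
        values = pd.DataFrame(np.where(det, raw, np.nan),
                              index=sample_ids, columns=all_ids)
        detected = pd.DataFrame(det, index=sample_ids, columns=all_ids)
        tables[tissue] = PeakTable(values=values, detected=detected,
                                   peak_meta=peak_meta.loc[all_ids],
                                   log_scale=False, tissue=tissue)
    return tables, reference, truth


def _long_living_flags(species: pd.DataFrame) -> np.ndarray:
    """1.0 for species with MLS > 0.9 × clade maximum, else 0.0."""
    out = np.zeros(len(species))
    for clade, grp in species.groupby("clade"):
        thr = 0.9 * grp["mls"].max()
        out[species.index.get_indexer(grp.index[grp["mls"] > thr])] = 1.0
    return out


# ---------------------------------------------------------------------------
# enzymes
# ---------------------------------------------------------------------------

def generate_enzyme_tables(
    truth: GroundTruth,
    reference: pd.DataFrame,
    n_enzymes: int = 908,
    enzyme_effect: float = 0.5,
    links_mean: float = 6.0,
    lifespan_fraction: float = 0.12,
    n_terms: int = 30,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate enzyme→lipid links, per-branch dN/dS, and term annotations.

    A ``lifespan_fraction`` of enzymes draws most of its lipid links from
    the planted predictor compounds and has its long-living-branch dN/dS
    multiplied by ``(1 - enzyme_effect)``; the short-living branch is
    left unshifted.  Term annotations concentrate the affected enzymes in
    a few functional terms so the term network has planted modules.
    """
    if n_enzymes < 1:
        raise ValueError("n_enzymes must be >= 1")
    if not (0.0 <= enzyme_effect < 1.0):
        raise ValueError("enzyme_effect must be in [0, 1)")
    rng = np.random.default_rng(seed)
    compounds = reference.index.to_numpy()
    pred = np.array([c for c in truth.predictor_compounds if c in set(compounds)])
    n_life = int(round(lifespan_fraction * n_enzymes)) if len(pred) else 0
    terms = np.array([f"T{k:03d}" for k in range(n_terms)])

    rows, life_ids = [], []
    for e in range(n_enzymes):
        eid = f"E{e:04d}"
        is_life = e < n_life
        n_links = 1 + int(rng.poisson(links_mean))
        if is_life:
            life_ids.append(eid)
            k_pred = min(len(pred), max(1, int(round(0.6 * n_links))))
            links = set(rng.choice(pred, size=k_pred, replace=False))
            rest = np.setdiff1d(compounds, list(links))
            extra = min(n_links - k_pred, len(rest))
            if extra > 0:
                links |= set(rng.choice(rest, size=extra, replace=False))
            my_terms = rng.choice(terms[:max(8, n_terms // 4)],
                                  size=min(3, 1 + int(rng.integers(3))), replace=False)
        else:
            links = set(rng.choice(compounds, size=min(n_links, len(compounds)),
                                   replace=False))
            my_terms = rng.choice(terms, size=1 + int(rng.integers(3)), replace=False)
        dnds_short = float(rng.gamma(2.0, 0.15))
        dnds_long = float(rng.gamma(2.0, 0.15))
        if is_life:
            dnds_long *= (1.0 - enzyme_effect)
        rows.append({
            "enzyme_id": eid,
            "linked_lipids": ";".join(sorted(links)),
            "dnds_long": dnds_long,
            "dnds_short": dnds_short,
            "terms": ";".join(sorted(my_terms)),
        })
    table = pd.DataFrame(rows).set_index("enzyme_id")
    truth.enzyme_effect = float(enzyme_effect)
    truth.lifespan_enzymes = tuple(life_ids)
    return table, truth


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_dataset(outdir, tables: dict, cohort: Cohort, reference: pd.DataFrame,
                  truth: GroundTruth, config: dict | None = None) -> None:
    """Write peak tables, metadata and a JSON truth sidecar as TSV/JSON."""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.species.to_csv(out / "species.tsv", sep="\t")
    cohort.samples.to_csv(out / "samples.tsv", sep="\t")
    reference.to_csv(out / "lipid_reference.tsv", sep="\t")
    for tissue, table in tables.items():
        table.values.to_csv(out / f"peaks_{tissue}.tsv", sep="\t")
        table.detected.astype(int).to_csv(out / f"detected_{tissue}.tsv", sep="\t")
    first = next(iter(tables.values()))
    first.peak_meta.to_csv(out / "peak_meta.tsv", sep="\t")
    sidecar = {
        "config": config or {},
        "truth": {
            "predictor_peaks": list(truth.predictor_peaks),
            "predictor_signs": truth.predictor_signs,
            "predictor_compounds": list(truth.predictor_compounds),
            "confounded_peaks": truth.confounded_peaks,
            "effect_size": truth.effect_size,
            "tissue_effect": truth.tissue_effect,
            "enzyme_effect": truth.enzyme_effect,
            "lifespan_enzymes": list(truth.lifespan_enzymes),
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
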