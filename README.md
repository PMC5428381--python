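# lifelipid

Cross-clade lipidome analysis of mammalian maximal lifespan (MLS).

Maximal lifespan is a stable species trait that varies more than
ten-fold even between closely related mammals. One way to look for the
molecular correlates of that variation is comparative tissue
lipidomics: measure thousands of lipid peaks in many tissues of many
species from several clades, and ask whether lipid concentrations can
identify the exceptionally long-living species of each clade — and if
so, which lipids carry the signal and whether the enzymes linked to
them evolve under stronger purifying selection in long-living lineages.

`lifelipid` implements that analysis as a tested, reusable pipeline for
researchers in comparative metabolomics and the biology of aging:

* **Synthetic cohorts** with planted ground truth: 3 clades (rodents,
  primates, bats), 35 species, 6 tissues, internal-standard variation,
  missingness, confounder-driven lipids, and predictor lipids whose
  long-living shift has the same sign in every clade.
* **Peak processing**: internal-standard (PC 34:0) normalization with
  log transform, 2.5 SD sample QC, 50%-per-species detection filtering,
  adduct annotation at 10 ppm, correlation/RT/compound-based merging of
  redundant peaks, cross-dataset peak matching.
* **Confounder filtering**: per-factor tests (t-test for sex and
  hibernation, ANOVA for diet, regression for BMR, body temperature,
  body mass, age) with Westfall–Young maxT permutation correction;
  lipids significant at p < 0.01 for *any* factor are removed.
* **Longevity classifiers**: logistic regression with an elastic-net
  penalty, 10 × 10 stratified cross-validation for parameter choice and
  AUC estimation, plus SVM-RFE and a linear elastic net on
  clade-normalized MLS as alternatives.
* **Clade hold-out**: graded removal (10%–100%) of one clade's
  individuals from training, coefficient-ranked merging of tissue
  datasets into brain and non-neural sets, and a label-permutation
  chance band.
* **Predictor characterization**: cross-clade concordance of
  concentration changes, lipid class/sub-class/pathway enrichment with
  empirical family-wise correction, directional shift tests,
  double-bond associations, tissue-overlap significance.
* **Enzyme evolution**: predictor-link-proportion selection of
  lifespan-related enzymes, one-sided rank-sum comparison of dN/dS
  between enzyme sets on long- vs short-living branches, and a
  shared-enzyme functional-term network.

## The model at the core

For tissue *t*, let `x_i ∈ R^p` be sample *i*'s standardized log lipid
concentrations and `y_i ∈ {0, 1}` mark individuals of *long-living*
species (MLS > 0.9 × clade maximum). The classifier solves

    min_{b0, b}  (1/n) Σ_i [ log(1 + exp(b0 + x_i·b)) − y_i (b0 + x_i·b) ]
                 + λ [ (1−α)/2 ‖b‖₂² + α ‖b‖₁ ]

with α (mixing) and λ (strength) chosen by 10 × 10 cross-validated AUC,
where AUC is the Mann–Whitney concordance P(score⁺ > score⁻). The
peaks with nonzero coefficients in the full-data refit are the *MLS
predictors* fed to the enrichment and enzyme-evolution stages.

## Worked example

```python
from lifelipid.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=1, stages=("simulate", "process", "confound", "fit"))
report = run_pipeline(cfg)
fit = report["stages"]["fit"]
print(f"mean CV AUC: {fit['mean_auc']:.3f}   max: {fit['max_auc']:.3f}")
for tissue, entry in fit["per_tissue"].items():
    print(f"{tissue:<11} AUC {entry['cv_auc']:.3f}  "
          f"predictors {entry['n_predictors']:>3} "
          f"({100 * entry['predictor_fraction']:.0f}%)  "
          f"recovery {entry['truth_recovery']:.2f}")
```

prints (seed 1):

```
mean CV AUC: 1.000   max: 1.000
liver       AUC 1.000  predictors  97 (35%)  recovery 1.00
muscle      AUC 1.000  predictors  90 (33%)  recovery 0.95
kidney      AUC 0.999  predictors  50 (18%)  recovery 0.85
heart       AUC 0.999  predictors  44 (16%)  recovery 0.80
cortex      AUC 1.000  predictors  62 (23%)  recovery 0.95
cerebellum  AUC 1.000  predictors  83 (31%)  recovery 0.95
```

Reading this: on the default synthetic benchmark (630 samples, 300
peaks per tissue, 20 planted cross-clade predictor lipids at effect
size 2), the cross-validated classifier separates long-living species
essentially perfectly in every tissue, and the refit model's nonzero
coefficients recover 80–95% of the planted predictor lipids; the extra
selected peaks are the elastic net's usual correlated passengers.

The same objects are available statsmodels-style:

```python
from lifelipid import LongevityClassifier
res = LongevityClassifier.from_table(table, cohort).fit_cv(seed=1)
print(res.summary())          # alpha, lambda, CV AUC, selected peaks
```

And from a shell:

```bash
lifelipid simulate --seed 1 --out data/          # TSV peak tables + truth
lifelipid run --seed 1 --out runs/demo           # full pipeline, report.json
```

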