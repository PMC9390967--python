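# radstab

Robustness-aware CT radiomics pipeline for predicting binary treatment
response from lesion imaging, built end-to-end on synthetic cohorts:

1. **synth** — seeded synthetic CT-lesion cohorts (ellipsoidal lesions,
   Gaussian-random-field texture, acquisition noise) with test–retest
   replicate pairs.
2. **preprocess** — window/level (fixed or adaptive), histogram
   equalisation, Gaussian denoising, selection of the 3 consecutive
   axial slices with maximal tumour area, resampling.
3. **perturb** — the three perturbation families used for robustness
   testing: axial slice spacing (S: 1/2/3/5 mm), in-plane rotation
   (R: ±15°, ±30°) and ROI contour variation (Seg: ±2 mm morphology).
4. **features** — from-scratch radiomics extractor: 14 shape, 18
   first-order, 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM features
   on the original image (107) plus the 93 non-shape features on each of
   8 coif1 stationary-wavelet sub-bands (744), 851 columns total.
5. **robustness** — ICC(2,1) per feature per perturbation family;
   features are retained iff ICC > 0.75 in *every* family; zero-MAD
   removal; train-fitted standardisation.
6. **select** — 13 feature-selection methods: CHSQ, RELF, MIM, FSCR,
   MIFS, GINI, ICAP, JMI, CIFE, CMIM, DISR, MRMR, TSCR, plus a
   recursive-feature-addition wrapper.
7. **grid** — SMOTE rebalancing, stratified k-fold CV, the extractor ×
   selector × classifier model grid (7 × 13 × 12 = 1092 combinations
   with the full registry), best model by highest mean AUC with RSD
   (= sd/mean × 100) breaking ties, confusion-matrix metrics.
8. **cli** — YAML-driven orchestration with a hashed run manifest.

All leakage-sensitive steps (standardisation, SMOTE, feature selection)
are fitted strictly inside training folds.

## CLI

```bash
radstab all config.yaml           # simulate -> extract -> perturb ->
                                  # robustness -> grid -> report
radstab simulate config.yaml      # or run stages individually
```

Minimal config:

```yaml
seed: 1                 # mandatory; no silent clock seeding
outdir: runs/demo
synth:
  n_responsive: 20
  n_unresponsive: 12
extract:
  extractors: [radiomics, radiomics-nowavelet]
grid:
  n_folds: 5
  n_select: 5
```

Artifacts land under `outdir/`: NIfTI cohort + manifest CSV, per-extractor
feature CSVs, long-format ICC report, retained-feature manifests, the
grid CSV with per-fold AUCs, selector × classifier AUC heatmap CSVs, the
best-model JSON and a report JSON with pooled out-of-fold confusion
metrics. Every stage appends a config snapshot and SHA-256 output hashes
to `run_manifest.json`; rerunning with the same config and seed
reproduces identical tables.

## Library usage

```python
from radstab.synth import CohortSpec, generate_cohort
from radstab.preprocess import PreprocessConfig, preprocess_sample
from radstab.features import ExtractionConfig, build_feature_table
from radstab.grid import GridConfig, run_grid, select_best

samples = generate_cohort(CohortSpec(n_responsive=20, n_unresponsive=12, seed=0))
slabs = [preprocess_sample(s, PreprocessConfig()) for s in samples]
table = build_feature_table(slabs, ExtractionConfig())
rows = run_grid({"radiomics": table}, [s.label for s in samples],
                ["MRMR", "RELF"], ["NearestNeighbors", "LogisticRegression"],
                GridConfig(n_folds=5, n_select=5, seed=0))
print(select_best(rows).name)
```
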