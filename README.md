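# noduletex

A tested, reusable pipeline for 2D CT lung-nodule radiomics: synthetic
part-solid nodule cohorts, a semi-automatic segmentation surrogate,
61 texture/intensity features, repeated cross-validation LASSO feature
importance, Youden-cutoff binarization with univariate and stepwise logistic
modelling, and paired reader-study statistics (McNemar, paired-difference
CIs, DeLong AUC comparison).

Because the original single-institution CT data are not public, every stage
is driven by a seeded synthetic cohort generator (`synthetic_cohort`) that
reproduces the assumed statistical structure: a 16/48 class split,
part-solid ground-glass intensity ranges (lung ≈ −850 HU, ground-glass
≈ −600 HU, solid ≈ −50 HU), 1024-matrix geometry (≈0.337 mm pixels), and a
positive class with higher ROI entropy and more negative coefficient of
variation.

## Modules

| module | contents |
| --- | --- |
| `noduletex.synthetic_cohort` | `CohortSpec`, nodule/cohort generators, synthetic feature tables and reader predictions |
| `noduletex.imaging_roi` | `ImagePatch`/`RoiMask`, NIfTI I/O, rectangle-seeded segmentation surrogate, max-solid-slice selection |
| `noduletex.texture_features` | quantization, GLCM/GLRLM/GLSZM/NGTDM matrices, the 61-feature registry, reader averaging |
| `noduletex.feature_selection` | repeated-CV L1 logistic importance counts, top-k selection, radiomics score |
| `noduletex.cutoff_models` | Youden cutoffs, binarization, univariate/stepwise logistic with Wald inference, ROC/AUC (DeLong CI) |
| `noduletex.reader_eval` | confusion metrics, paired McNemar, paired-difference CIs, paired AUC comparison |
| `noduletex.config` / `noduletex.pipeline` / `noduletex.cli` | configuration, orchestration and the `noduletex` command |

## CLI

Every stage is a subcommand reading/writing plain CSV/JSON (images and masks
as NIfTI):

```sh
noduletex run-all --seed 7 --out out/                 # full synthetic analysis
noduletex simulate --config cfg.yaml --out cohort/    # images + manifest
noduletex extract  --manifest cohort/manifest.csv --out features.csv
noduletex select   --features features.csv --seed 7 --out sel/
noduletex cutoffs  --features features.csv --selected sel/selected.json --out cutoffs.csv
noduletex fit      --features features.csv --selected sel/selected.json --out model.json
noduletex evaluate-readers --table readers.csv --out report.csv
```

Exit codes: 0 ok, 1 validation error, 2 runtime error. A configuration must
carry an explicit `seed`; reruns with the same configuration are
byte-identical. Example configuration:

```yaml
seed: 7
cohort: {n_positive: 16, n_negative: 48, image_size: 256, axis_range: [8, 30]}
texture: {n_levels: 32, log_base: e}
selection: {n_folds: 10, n_repeats: 10, top_k: 10}
model: {p_enter: 0.05, p_remove: 0.1}
```

## Conventions and defaults

- Quantization: 32 equal-width bins over the ROI HU range; entropy in
  natural log (base-2 selectable); recorded in output metadata.
- GLCM: distance 1, four directions, symmetric, direction-pooled.
  GLRLM: four directions, features direction-averaged. GLSZM/NGTDM:
  8-connectivity. Coefficient of variation uses the population SD.
- Undefined features (zero-variance denominators) are emitted as missing,
  never as 0.
- The L1 logistic path is solved by accelerated proximal gradient descent
  (exact zeros via soft-thresholding); the per-fit penalty is chosen by
  inner 5-fold cross-validated deviance over a 50-point grid spanning four
  decades below the all-zero penalty.
- Stepwise logistic uses Wald p-values (enter ≤ 0.05, remove > 0.1) with a
  likelihood-ratio fallback for separation-degenerate terms, flagged in the
  result.
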