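# pbsikit

Person-based similarity analysis of regional brain morphometry, as a tested,
reusable pipeline:

- **synthetic** — cohort and gene-expression generators with an explicit
  generative model and full ground-truth records (multi-site batch effects,
  linear age/sex/TIV effects, group- and age-dependent subject heterogeneity,
  planted spatially-associated genes).
- **harmonize** — parametric empirical-Bayes batch harmonization (ComBat),
  the principal-component covariance extension (CovBat) as a sensitivity
  option, and Bland–Altman agreement.
- **pbsi** — person-based similarity index (mean pairwise Spearman
  correlation of subject profiles within a diagnostic group), exact
  leave-one-region-out regional contributions, the ASD−NC Δcontribution map,
  and covariate-adjusted group/correlation statistics with Bonferroni
  region-wise control.
- **brainage** — brain-age modelling on regional-contribution features with
  three linear-kernel regressors (epsilon-SVR with nested grid search,
  sparse-Bayesian relevance vector regression on a precomputed kernel, and
  Gaussian-process regression), age-stratified shuffled 10-fold
  cross-validation, brain-age-gap computation, the ±0.5·SD
  delayed/premature-development split, and cognition comparisons.
- **transcriptomics** — scaled-robust-sigmoid normalization, coordinate-based
  sample-to-region assignment (nearest voxel within 3 mm), region-level
  aggregation, Benjamini–Hochberg FDR, and per-gene Spearman association with
  the Δcontribution map.
- **pipeline / cli** — end-to-end orchestration from a single YAML config
  with per-stage persistence and full seed-determinism.

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests for the documented
invariants (rank invariance, delta antisymmetry, EB shrinkage direction,
no-leakage cross-validation, determinism), independent brute-force oracles in
`tests/oracles.py`, and `tests/test_acceptance.py` with one test per
acceptance criterion.

## Command line

```sh
pbsikit simulate  --spec spec.yaml --out data/
pbsikit harmonize --profiles data/profiles.csv --phenotypes data/phenotypes.csv \
                  --method combat --covariates age,sex,tiv --out harmonized.csv
pbsikit pbsi      --profiles harmonized.csv --phenotypes data/phenotypes.csv \
                  --out scores.csv --contrib-out contributions.csv
pbsikit brainage  --features contributions.csv --phenotypes data/phenotypes.csv \
                  --model rvr --out brainage.csv --report report.json
pbsikit associate --delta delta_contributions.csv --expression expression.csv \
                  --out genes.csv
pbsikit run       --config run.yaml
```

A minimal `run.yaml` for a fully synthetic end-to-end run:

```yaml
out_dir: out/
seed: 1
synthetic:
  cohort: {n_per_group: 60, n_regions: 40, n_sites: 3}
  expression: {n_genes: 200, n_planted: 20, rho_target: 0.6}
harmonization: {method: combat, covariates: [age, sex, tiv]}
brainage: {model: rvr, n_folds: 10, n_shuffles: 10}
fdr: 0.05
```

## Notes and caveats

- Subject-level heterogeneity in the synthetic generator is Gaussian; this is
  an explicit assumption, not an estimate.
- Gene–map associations are plain rank correlations across regions; no
  spatial-autocorrelation-preserving null (spin test) is applied.
- ComBat here is the parametric empirical-Bayes variant; non-parametric,
  GAM, longitudinal and reference-batch variants are out of scope.
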