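# tximpute

Cross-tissue transcriptome imputation: predict gene expression in a
hard-to-sample target tissue (the motivating case is lung) from blood
RNA-seq, with built-in cross-validation, external replication testing,
and downstream differential-expression analysis on the imputed profiles.

Lung tissue is rarely available for molecular studies of non-cancerous
lung disease, while blood RNA-seq exists at scale. When paired
blood/lung samples are available for training, a surprisingly simple
model imputes a large fraction of the lung transcriptome: take the top
*K* principal components of standardized blood expression and fit, per
lung gene *g*, an ordinary least-squares regression

&nbsp;&nbsp;&nbsp;&nbsp;*Y*<sub>*g*</sub> = β₀ + β₁*X*₁ + … + β<sub>*K*</sub>*X*<sub>*K*</sub> + ε,

where *X*₁…*X*<sub>*K*</sub> are a subject's blood PC scores. The package provides:

- **`simulate_*`** — a latent-factor generator for paired two-tissue data
  with known per-gene imputability *f* (the fraction of target-tissue
  variance shared with blood, so √f is the analytic accuracy ceiling),
  negative-binomial count matrices, and case-control cohorts with effects
  embedded either in shared factors (recoverable from blood) or in
  lung-private residuals (not recoverable) — ground truth for every claim.
- **`train_bundle` / `impute`** — fit the PCA + per-gene OLS model on
  paired samples; apply it to new blood cohorts after gene harmonization;
  save/load bundles as inspectable text.
- **`cross_validate` / `select_genes`** — k-fold CV with PCA refit inside
  every training split; per-gene accuracy is the squared Pearson
  correlation of observed vs out-of-fold predicted expression; genes are
  *reliably imputed* when mean fold R² ≥ 0.01 and BH q ≤ 0.05 (with
  positive pooled correlation).
- **`evaluate_replication`** — Fisher-z comparison of training vs
  replication-cohort accuracy; a gene replicates when p > 0.05 (no
  significant loss of accuracy) and r ≥ 0.1 in the replication set.
- **`fit_dge` / `logfc_concordance`** — covariate-adjusted per-gene OLS
  differential expression (case status + sex, age, four leukocyte
  percentages) and Pearson correlation of log2 fold changes against a
  reference DE table.
- **`counts_to_cpm`, `filter_low_expression`, `log2_transform`,
  `quantile_normalize`, `tmm_factors`, `adjust_batches`** — the RNA-seq
  pre-processing stages, including a TMM implementation that agrees with
  edgeR to ~1e-12.

## Worked example

`examples/` contains one short script per capability. Cross-validated
gene selection on simulated data with graded imputability
(`examples/02_cross_validation.py`):

```sh
$ python examples/02_cross_validation.py
278 of 400 genes selected as reliably imputed
imputability f | mean CV r | ceiling sqrt(f) | selected
           0.0 |    -0.026 |           0.000 |      9%
          0.05 |     0.151 |           0.224 |     69%
           0.2 |     0.399 |           0.447 |    100%
           0.5 |     0.686 |           0.707 |    100%
```

Each row is a block of 100 lung genes with the stated true shared
fraction *f*: mean cross-validated accuracy rises with *f* and stays
below the analytic ceiling √f, and genes with no shared signal (f = 0)
are selected at roughly the nominal false-discovery rate. The
replication example (`examples/03_replication.py`) then splits a cohort
in half and shows ~93% of CV-selected genes replicating, with the
imputed profiles far more concordant with observed lung than any single
blood gene (median r 0.42 vs 0.01).

A thin CLI mirrors the library (`tximpute train/impute/cv/replicate/
dge/concordance/normalize/simulate`); run `tximpute --help`.

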