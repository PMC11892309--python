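# Methods

## The imputation model

The model treats cross-tissue imputation as principal-component
regression. Let **B** be the n × p matrix of blood expression on a
log-like scale (log2 CPM or quantile-normalized values), with subjects as
rows. Each blood gene is standardized by its training mean and SD, and
the top K right singular vectors of the standardized matrix form the
rotation; a subject's PC scores are the projection of their standardized
blood profile onto that rotation. For each target-tissue (lung) gene g,
ordinary least squares fits

    Y_g = beta_0 + beta_1 X_1 + ... + beta_K X_K + eps

on the K scores. A trained bundle therefore consists of the per-gene
means/SDs, the rotation, and one coefficient vector per lung gene; it is
serialized as plain tab-delimited text plus a JSON sidecar carrying a
format version, so bundles are inspectable and portable.

Modeling choices that were genuinely open:

- **Standardization before PCA.** Genes are z-scored, not merely
  centered. Without scaling, the first components are dominated by the
  most variable (usually most highly expressed) genes; z-scoring makes
  the components a democratic summary of co-expression, and the stored
  means/SDs make projection of new cohorts well defined. Centering-only
  remains possible by pre-scaling the input.
- **OLS rather than a penalized fit.** With K in the tens, orthogonal
  predictors, and hundreds of subjects, least squares is well
  conditioned; penalization adds a tuning dimension without improving
  this model class.
- **Deterministic component signs.** Each component is flipped so its
  largest-magnitude loading is positive; SVD sign ambiguity would
  otherwise make bundles platform-dependent.
- **Missing genes at projection time** contribute 0 after
  standardization — i.e. they sit at the training mean — with a hard
  floor of 50% gene coverage. Imputation degrades gracefully when the
  new cohort's annotation differs, but refuses to run from a minority of
  the model's genes.
- **K defaults to 20 components**; the CLI sweep (`--pcs 5,10,20,40`)
  reports selection counts, CV accuracy, and replication per K, since
  more components reliably help in-sample but not necessarily in
  replication or downstream signals.

## Cross-validation and gene selection

Per-gene accuracy is the **squared Pearson correlation** between
observed and out-of-fold predicted expression (not 1 − SSE/SST): the
selection threshold R² ≥ 0.01 used in the imputation literature is the
square of the replication threshold r ≥ 0.1 only under this reading, and
it is invariant to affine miscalibration of the predictions. The PCA and
all gene models are refit inside every training split; nothing from a
validation fold touches its predictions. Fold assignment is a seeded
balanced partition at subject level.

The point estimate of accuracy is the fold-averaged r (and r²),
following standard practice; the p-value instead comes from the
correlation over the *pooled* out-of-fold predictions (one well-powered
test at n = all subjects, via t = r·sqrt((n−2)/(1−r²)) on n−2 df),
because per-fold p-values at n/k subjects are underpowered and averaging
p-values has no clean null. BH q-values are computed across genes with a
valid test. Selection requires mean fold R² ≥ 0.01, q ≤ 0.05, **and
pooled r > 0** — the positivity guard is an extension (toggleable off in
`select_genes`) that keeps systematically anti-correlated predictions
from passing a squared threshold.

A calibration note: under a permutation null, pooled out-of-fold
correlations are slightly *negative* (training-fold means move opposite
to held-out means — a known CV artifact), so two-sided q-values pick up
a negative tail. The positivity guard absorbs this: the selected
fraction among truly null genes stays at or below the nominal rate.

## Replication testing

Training accuracy (pooled CV r at n_train subjects) is compared with the
replication-cohort accuracy (imputed vs observed target-tissue r at
n_rep subjects) by Fisher's z: z = (atanh r₁ − atanh r₂) /
sqrt(1/(n₁−3) + 1/(n₂−3)). A gene replicates when p > 0.05 (strict; no
significant difference in accuracy) and r_rep ≥ 0.1 (inclusive).
Replication p-values are deliberately left uncorrected: multiplicity
correction would *relax* the no-difference requirement. n_train is the
number of subjects contributing pooled out-of-fold predictions (the full
training cohort) and is recorded per gene for transparency.

## Differential expression on imputed profiles

Per gene, expression is regressed on a case indicator plus covariates
(sex as an indicator, age, and the four leukocyte percentages as
continuous terms); the status coefficient is the log2 fold change
(case − control) and its t-test at residual df gives the p-value, BH-
corrected across genes. The fits are exact per-gene OLS computed for all
genes simultaneously from one shared design; no cross-gene variance
moderation is applied. Moderation shrinks variance estimates but leaves
coefficient estimates untouched, so the fold-change concordance
statistic — the Pearson correlation of log2FC vectors against a
reference DE table — is identical to what a moderated fit would give.
"After FDR correction" is interpreted as gating the concordance gene set
on the *reference* table's q ≤ 0.05 (default), with an `all_shared` mode
provided, since which side's FDR should gate the set is ambiguous.

Cohort construction mirrors a COPD blood-cohort application: cases are
FEV1/FVC < 0.7 (strict), subjects older than 70 are excluded (strict,
matching the age ceiling of typical training cohorts), samples with
missing spirometry are labeled unknown and dropped with a warning.

## Normalization stages

- **CPM** uses full column sums computed *before* any gene filtering:
  library size is a property of sequencing depth, not of the retained
  gene set.
- **Low-expression filter** removes genes with CPM ≤ 1 in ≥ 100 samples
  (both configurable); if the cohort is smaller than the sample floor no
  gene can meet the rule and a warning is emitted.
- **log2 transform** uses pseudocount 1, mapping CPM 0 to 0.
- **Quantile normalization** substitutes per-rank means of the sorted
  columns; ties receive the mean of the target values over their tied
  ranks, which makes the map deterministic. With ties present the
  columns no longer share an exact sorted multiset, but column sums (and
  means) are preserved exactly.
- **TMM factors** implement the trimmed-mean-of-M-values estimator with
  the canonical defaults (30% two-sided trim on M, 5% on A, precision
  weights from the delta-method binomial variance, reference = sample
  whose upper quartile of library-scaled counts is closest to the mean,
  geometric-mean-1 rescaling). The implementation is cross-checked in
  the test suite against both an independent step-by-step transcription
  and edgeR's `calcNormFactors`, agreeing to ~1e-12.
- **Batch adjustment** is a per-gene location/scale standardization
  (each batch mapped to the gene's pooled mean and SD; mean-centering
  only where a batch has zero variance). It intentionally omits the
  empirical-Bayes shrinkage of ComBat-style methods: for the moderate,
  well-replicated batches the simulator produces the two coincide in
  expectation, and the location/scale version is exactly derivable.

## The synthetic-data generator

`simulate_paired` draws q standard-normal latent factors per subject.
Blood gene j is l_j·Z + noise_sd·eps with a unit-norm loading vector
l_j; lung gene g is sqrt(f_g)·(u_g·Z) + sqrt(1−f_g)·eps with unit-norm
u_g, so each lung gene has population variance exactly 1 and shares
exactly fraction f_g of it with the blood-visible factors. This makes
sqrt(f) an analytic ceiling on achievable imputation accuracy, and the
recorded f the ground truth for recovery and calibration tests. Loading
vectors are row-normalized (one unit-norm vector per gene): this is what
delivers the stated per-gene variance bookkeeping; normalizing across
genes instead would make per-gene signal variance shrink as q/p and
drown the signal in noise.

Defaults (q = 10 factors, blood noise SD 0.5, 1000 blood × 500 lung
genes, n = 300 subjects) are sized so that blood carries the factors
essentially noiselessly in aggregate while individual blood genes remain
noisy — the regime in which imputation visibly beats single-gene
blood-lung concordance.

`simulate_case_control` reserves the last latent factor as a disease
axis. In the `shared_factor` route, cases have that factor shifted by
`factor_shift` (default 2.0); an affected lung gene's loading on the
axis is set to delta/(sqrt(f)·factor_shift) (requiring |delta| <
sqrt(f)·factor_shift) and its remaining loadings renormalized, so its
true case−control log2FC is exactly delta while null genes carry exactly
0; blood genes load on the axis generically, carrying a sign-mixed,
attenuated trace. In the `lung_private` route the effect is added to
lung residuals only, and no blood-based predictor can recover it — the
negative control separating genuine cross-tissue recovery from label
leakage. Each cohort comes with an independent paired training set drawn
from the same loadings (the supported way to train the model that will
be applied to the cohort). Metadata covariates (age uniform 45–80, sex,
two batches, leukocyte percentages at hemogram-typical means, FEV1/FVC
consistent with status) are independent of status by default; an
`age_case_shift` knob introduces deliberate confounding for sensitivity
checks.

`simulate_counts` draws negative-binomial counts with log-normal gene
means and uniform per-sample library multipliers — enough structure to
exercise CPM, filtering, TMM, and quantile normalization, with a Poisson
limit at small dispersion.

What the simulator does *not* emulate: count-level noise in the paired
(Gaussian, log-scale) data, gene-gene correlation beyond the factor
structure, gene-length effects, outlier samples, or real annotation
drift between cohorts. Passing tests therefore demonstrate correctness
and calibration of the algorithms under the stated generative model, not
performance on any particular real cohort.

## Problem sizes, tolerances, determinism

Test and acceptance runs use n = 200–600 subjects, 400–1000 blood genes,
and up to 2000 target genes — large enough that block-level means are
stable to a few hundredths while the full suite stays fast. Every
stochastic step is driven by an explicit seed (the CLI makes the seed a
required argument); identical seeds give bit-identical outputs. Linear
algebra uses SVD/`lstsq` (no explicit inverses except the small K × K
and design Gram matrices); rotation orthonormality is enforced at 1e-8;
rank-deficient designs raise rather than silently pseudo-inverting;
correlation of a constant vector is NaN and excluded from FDR (detected
by exact max = min, not a tolerance). The Fisher-z vectorized path
clamps |r| at 1 − 1e-12 to keep atanh finite; the scalar API refuses
|r| = 1 outright.

## Known limitations

- The model is linear and population-specific: a bundle transfers only
  to cohorts drawn from (approximately) the training population, after
  gene harmonization by version-stripped ID intersection.
- Plain OLS t-tests in `fit_dge` are slightly anticonservative at very
  small n compared with moderated tests; fold-change estimates are
  unaffected.
- The location/scale batch adjustment does not pool information across
  genes and can overcorrect genes whose within-batch variance is
  estimated from few samples.
- Replication requires the gene to be measured in the replication lung
  matrix; missing genes are excluded and counted, not imputed.
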