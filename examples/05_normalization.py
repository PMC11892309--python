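"""The RNA-seq pre-processing stages: CPM, filtering, log2, quantile, TMM.

Simulates a negative-binomial count matrix with unequal library sizes and
walks it through the normalization pipeline used before training or
applying imputation models.
"""

import numpy as np

import tximpute as tx

counts = tx.simulate_counts(
    n_genes=2000, n_samples=150, dispersion=0.2, lib_size_range=(0.5, 1.5), seed=8
)
print(f"raw counts: {counts.n_genes} genes x {counts.n_samples} samples, "
      f"library sizes {counts.values.sum(0).min():.0f}-{counts.values.sum(0).max():.0f}")

factors = tx.tmm_factors(counts)
print(f"TMM scaling factors: range {factors.min():.3f}-{factors.max():.3f}, "
      f"geometric mean {np.exp(np.log(factors).mean()):.6f}")

cpm = tx.counts_to_cpm(counts)
filtered = tx.filter_low_expression(cpm, cpm_threshold=1.0, min_samples=100)
print(f"low-expression filter (CPM <= 1 in >= 100 samples): "
      f"{cpm.n_genes} -> {filtered.n_genes} genes")

logged = tx.log2_transform(filtered)
normalized = tx.quantile_normalize(logged)
col_means = normalized.values.mean(axis=0)
print(f"after log2 + quantile normalization, column means span "
      f"{col_means.min():.6f}-{col_means.max():.6f}")
# all samples now share one empirical distribution (equal means), library
# composition bias is summarized by the TMM factors, and the matrix is
# ready for standardized PCA
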