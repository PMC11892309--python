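"""Normalization and filtering for bulk RNA-seq expression matrices.

Implements the pre-processing stages the imputation workflow relies on:
counts-per-million scaling, low-expression filtering, log2 transform,
quantile normalization, TMM (trimmed mean of M-values) between-sample
scaling factors, and a location/scale batch adjustment.

The batch adjustment is a plain per-gene, per-batch standardization
rescaled to the pooled moments. It deliberately does not shrink batch
effects across genes the way empirical-Bayes methods (ComBat) do; for the
moderate batch effects the simulator produces the two behave similarly,
and the location/scale version is exactly reproducible from first
principles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix


def counts_to_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale raw counts to counts-per-million using full column totals.

    Library size is the column sum of the matrix as given — compute CPM
    before any gene filtering so it reflects true sequencing depth.
    """
    if m.unit != "counts":
        raise ValueError(f"counts_to_cpm expects unit 'counts', got {m.unit!r}")
    totals = m.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"zero library size for sample(s) {[m.sample_ids[i] for i in zero[:5]]}"
        )
    return m.with_values(m.values / totals * 1e6, unit="cpm")


def filter_low_expression(
    m: ExpressionMatrix, cpm_threshold: float = 1.0, min_samples: int = 100
) -> ExpressionMatrix:
    """Drop genes with CPM <= *cpm_threshold* in at least *min_samples* samples.

    Gene order is preserved. If *min_samples* exceeds the sample count no
    gene can meet the removal rule; a warning is emitted and the matrix is
    returned unchanged.
    """
    if m.unit != "cpm":
        raise ValueError(f"filter_low_expression expects unit 'cpm', got {m.unit!r}")
    if min_samples > m.n_samples:
        warnings.warn(
            f"min_samples={min_samples} exceeds sample count {m.n_samples}; "
            "no genes removed",
            stacklevel=2,
        )
        return ExpressionMatrix(m.data.copy(), m.unit)
    n_low = (m.values <= cpm_threshold).sum(axis=1)
    keep = n_low < min_samples
    return ExpressionMatrix(m.data.loc[keep], m.unit)


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount); a pseudocount of 1 maps CPM 0 to 0."""
    if m.unit != "cpm":
        raise ValueError(f"log2_transform expects unit 'cpm', got {m.unit!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return m.with_values(np.log2(m.values + pseudocount), unit="log2cpm")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common empirical distribution.

    Each column is replaced rank-by-rank with the mean of the sorted
    columns; tied values within a column receive the mean of the target
    values over their tied ranks, so the map is deterministic and
    order-independent.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    v = m.values
    target = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        col = v[:, j]
        idx = np.argsort(col, kind="stable")
        assigned = np.empty_like(target)
        assigned[idx] = target
        # average target values over tie groups
        ties = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = ties.to_numpy()
    return m.with_values(out, unit="normalized")


def tmm_factors(
    m: ExpressionMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values between-sample scaling factors.

    The reference sample is the one whose upper quartile of library-size-
    scaled counts is closest to the mean upper quartile. For every sample,
    gene-wise log2 ratios M and log2 abundances A against the reference are
    computed over genes with nonzero counts in both; the top and bottom
    *trim_m* of M and *trim_a* of A are trimmed; the factor is 2 to the
    precision-weighted mean of the surviving M values, with weights from
    the binomial (delta-method) variance approximation. Factors are
    rescaled to geometric mean 1.
    """
    if m.unit != "counts":
        raise ValueError(f"tmm_factors expects unit 'counts', got {m.unit!r}")
    if m.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    counts = m.values
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = [m.sample_ids[i] for i in np.flatnonzero(lib == 0)]
        raise ValueError(f"sample(s) with all-zero counts: {bad[:5]}")
    counts = counts[(counts > 0).any(axis=1)]  # genes zero in every sample carry no information
    scaled = counts / lib
    f75 = np.quantile(scaled, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    log_factors = np.array(
        [
            _tmm_pair(counts[:, j], lib[j], counts[:, ref], lib[ref], trim_m, trim_a)
            for j in range(counts.shape[1])
        ]
    )
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=m.sample_ids, name="tmm_factor")


def _tmm_pair(
    obs: np.ndarray,
    lib_obs: float,
    ref: np.ndarray,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    ok = (obs > 0) & (ref > 0)
    o, r = obs[ok], ref[ok]
    po, pr = o / lib_obs, r / lib_ref
    m_vals = np.log2(po / pr)
    a_vals = 0.5 * np.log2(po * pr)
    if m_vals.size == 0 or np.abs(m_vals).max() < 1e-10:
        return 0.0
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    w = 1.0 / v  # precision weights
    n = m_vals.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m_vals)
    rank_a = rankdata(a_vals)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 0.0
    f = float((w[keep] * m_vals[keep]).sum() / w[keep].sum())
    if not np.isfinite(f) or abs(f) < 1e-6:
        return 0.0
    return f


def adjust_batches(m: ExpressionMatrix, batches) -> ExpressionMatrix:
    """Location/scale batch adjustment.

    Per gene, each batch's values are standardized by the batch mean and SD
    and rescaled to the gene's pooled mean and SD. Genes with zero variance
    in any batch (or overall) fall back to mean-centering only; a constant
    gene therefore passes through unchanged.
    """
    batches = pd.Series(np.asarray(batches), index=m.sample_ids)
    if batches.isna().any():
        raise ValueError("every sample must carry a batch label")
    sizes = batches.value_counts()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        raise ValueError(f"batch(es) with fewer than 2 samples: {singletons}")
    v = m.values
    out = v.copy()
    pooled_mean = v.mean(axis=1)
    pooled_sd = v.std(axis=1, ddof=1)
    groups = {b: np.flatnonzero((batches == b).to_numpy()) for b in sizes.index}
    batch_sds = np.stack([v[:, idx].std(axis=1, ddof=1) for idx in groups.values()])
    scale_ok = (batch_sds > 0).all(axis=0) & (pooled_sd > 0)
    for idx in groups.values():
        block = v[:, idx]
        bmean = block.mean(axis=1, keepdims=True)
        bsd = block.std(axis=1, ddof=1, keepdims=True)
        centered = block - bmean
        adj = np.where(
            scale_ok[:, None],
            centered / np.where(bsd > 0, bsd, 1.0) * pooled_sd[:, None],
            centered,
        )
        out[:, idx] = adj + pooled_mean[:, None]
    return m.with_values(out, unit="normalized")
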