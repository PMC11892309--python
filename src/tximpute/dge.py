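"""Covariate-adjusted differential expression and fold-change concordance.

Per gene, expression (observed or imputed, on a log2-like scale) is
regressed on a case/control indicator plus covariates; the status
coefficient is the log2 fold change (case minus control) and its t-test
gives the per-gene p-value, BH-corrected across genes. The per-gene fits
are exact ordinary least squares, computed for all genes at once from one
shared design matrix; no cross-gene variance moderation is applied, which
leaves the fold-change estimates identical to what a moderated fit would
report and only the per-gene variance estimates less shrunken.

Cohort construction mirrors a COPD blood-cohort application: airflow
obstruction (FEV1/FVC < 0.7) defines cases, subjects older than 70 are
excluded to match the age range of typical training cohorts, and the
models adjust for sex, age, and four circulating leukocyte percentages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import row_correlations
from .crossval import bh_fdr
from .matrix import ExpressionMatrix

MAX_AGE_DEFAULT = 70.0
FEV1_FVC_THRESHOLD = 0.7
DEFAULT_COVARIATES = ("sex", "age", "pct_neut", "pct_lymph", "pct_mono", "pct_eos")


def filter_age(meta: pd.DataFrame, max_age: float = MAX_AGE_DEFAULT) -> list[str]:
    """Sample IDs with age <= max_age (strictly older subjects excluded)."""
    if "age" not in meta.columns:
        raise ValueError("metadata has no 'age' column")
    missing = meta.index[meta["age"].isna()].tolist()
    if missing:
        raise ValueError(f"samples with missing age: {missing[:10]}")
    return meta.index[meta["age"] <= max_age].tolist()


def copd_case_control(
    meta: pd.DataFrame, ratio_threshold: float = FEV1_FVC_THRESHOLD
) -> pd.Series:
    """Label samples case/control by the spirometric FEV1/FVC criterion.

    Case iff FEV1/FVC < threshold (strict); samples with a missing ratio
    are labeled ``unknown`` with a warning and excluded downstream.
    """
    if "fev1_fvc" not in meta.columns:
        raise ValueError("metadata has no 'fev1_fvc' column")
    ratio = meta["fev1_fvc"]
    if ratio.isna().all():
        raise ValueError("all FEV1/FVC ratios missing; no cases definable")
    if ratio.isna().any():
        warnings.warn(
            f"{int(ratio.isna().sum())} sample(s) with missing FEV1/FVC "
            "labeled 'unknown'",
            stacklevel=2,
        )
    status = pd.Series(
        np.where(ratio.isna(), "unknown", np.where(ratio < ratio_threshold, "case", "control")),
        index=meta.index,
        name="disease_status",
    )
    return status


def _build_design(
    status: pd.Series, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, list[str]]:
    n = len(status)
    cols = [np.ones(n), (status == "case").to_numpy(dtype=float)]
    names = ["intercept", "status"]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype == object:
                levels = sorted(col.dropna().unique())
                if len(levels) > 2:
                    raise ValueError(
                        f"categorical covariate {name!r} has {len(levels)} levels; "
                        "encode it numerically"
                    )
                col = (col == levels[-1]).astype(float)
            if col.isna().any():
                raise ValueError(f"covariate {name!r} has missing values")
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
    return np.column_stack(cols), names


def fit_dge(
    expr: ExpressionMatrix,
    status,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene OLS differential expression, case vs control.

    ``status`` holds 'case'/'control' (optionally 'unknown', dropped with a
    warning) per sample; ``covariates`` is an optional per-sample table
    aligned to the expression columns (string columns with two levels are
    dummy-coded). Returns a DataFrame with log2fc, t_stat, p, q per gene.
    """
    status = pd.Series(status, index=expr.sample_ids if not isinstance(status, pd.Series) else None)
    if isinstance(status.index, pd.RangeIndex):
        status.index = expr.sample_ids
    status = status.reindex(expr.sample_ids)
    if status.isna().any():
        missing = status.index[status.isna()].tolist()
        raise ValueError(f"samples without a status label: {missing[:10]}")
    usable = status.isin(["case", "control"])
    if (~usable).any():
        warnings.warn(
            f"dropping {int((~usable).sum())} sample(s) with unknown status",
            stacklevel=2,
        )
    samples = status.index[usable].tolist()
    status = status.loc[samples]
    for group in ("case", "control"):
        if (status == group).sum() < 2:
            raise ValueError(f"need at least 2 '{group}' samples")
    expr = expr.select_samples(samples)
    if covariates is not None:
        covariates = covariates.loc[samples]
    x, names = _build_design(status, covariates)
    n, p_dim = x.shape
    if np.linalg.matrix_rank(x) < p_dim:
        # identify a dependent column for the error message
        culprit = None
        for j in range(2, p_dim):
            others = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(x):
                culprit = names[j]
                break
        raise ValueError(
            f"collinear design matrix (dependent column: {culprit or 'unknown'})"
        )
    y = expr.values  # G x n
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ (x @ xtx_inv)  # G x p
    resid = y - beta @ x.T
    df = n - p_dim
    sigma2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, beta[:, 1] / se, np.nan)
    pvals = 2.0 * stats.t.sf(np.abs(t), df=df)
    pvals = np.where(np.isnan(t), np.nan, pvals)
    out = pd.DataFrame(
        {
            "log2fc": beta[:, 1],
            "t_stat": t,
            "p": pvals,
            "q": bh_fdr(pvals),
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )
    return out


def logfc_concordance(
    a: pd.DataFrame,
    reference: pd.DataFrame,
    gene_filter: str = "reference_significant",
    q_max: float = 0.05,
) -> tuple[float, float, int]:
    """Pearson correlation of log2 fold changes against a reference DE table.

    ``gene_filter='reference_significant'`` restricts to reference genes
    with q <= q_max; ``'all_shared'`` uses every shared gene. Returns
    (r, two-sided p, number of genes).
    """
    if gene_filter not in ("reference_significant", "all_shared"):
        raise ValueError(f"unknown gene_filter {gene_filter!r}")
    ref = reference.set_index("gene_id") if "gene_id" in reference.columns else reference
    if gene_filter == "reference_significant":
        if "q" not in ref.columns:
            raise ValueError("reference table needs a 'q' column for this filter")
        ref = ref[ref["q"] <= q_max]
    shared = [g for g in a.index if g in set(ref.index)]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes after filtering; need >= 10")
    x = a.loc[shared, "log2fc"].to_numpy(dtype=float)
    y = ref.loc[shared, "log2fc"].to_numpy(dtype=float)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(shared)
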