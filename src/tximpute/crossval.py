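"""k-fold cross-validation of the imputation model and gene selection.

Per-gene predictive accuracy is the squared Pearson correlation between
observed and out-of-fold predicted expression, averaged over validation
folds. A gene is deemed reliably imputed when its mean fold R-squared is
at least 0.01 and its Benjamini-Hochberg q-value (from the correlation
over pooled out-of-fold predictions) is at most 0.05 — the conventions of
the genotype-based imputation literature — with an additional guard that
the pooled correlation be positive, since a squared threshold would
otherwise admit systematically anti-correlated predictions.

The PCA and the per-gene regressions are refit inside every training
split, so no information from a validation fold leaks into its
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import correlation_pvalues, row_correlations
from .matrix import ExpressionMatrix
from .model import DEFAULT_N_COMPONENTS, fit_pca, project_pca, train_gene_models

R2_MIN_DEFAULT = 0.01
Q_MAX_DEFAULT = 0.05


def assign_folds(subject_ids, k: int = 5, seed: int = 0) -> pd.Series:
    """Random balanced partition of subjects into k folds (deterministic in seed).

    Assignment is at subject level, so paired samples from one subject stay
    in the same fold. Fold sizes differ by at most one.
    """
    subject_ids = list(subject_ids)
    n = len(subject_ids)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError(f"cannot split {n} subjects into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        labels[chunk] = fold
    return pd.Series(labels, index=subject_ids, name="fold")


def per_gene_accuracy(observed, predicted) -> tuple[float, float, float]:
    """(r, r^2, two-sided p) for one gene's observed vs predicted values."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError("observed and predicted must be 1-D of equal length")
    n = observed.size
    if n < 4:
        raise ValueError("need at least 4 paired values")
    if observed.std() == 0 or predicted.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(row_correlations(observed[None, :], predicted[None, :])[0])
    p = float(correlation_pvalues(np.array([r]), n)[0])
    return r, r * r, p


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    NaN entries (genes excluded from testing) stay NaN and do not count
    toward the number of tests.
    """
    p = np.asarray(pvals, dtype=float)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


@dataclass
class CVResult:
    """Per-gene cross-validation table plus the run's parameters.

    ``table`` columns: mean_fold_r, mean_fold_r2, pooled_r, pooled_p, q,
    selected, indexed by gene_id.
    """

    table: pd.DataFrame
    k: int
    seed: int
    n: int
    n_components: int
    r2_min: float = R2_MIN_DEFAULT
    q_max: float = Q_MAX_DEFAULT

    @property
    def selected_genes(self) -> list[str]:
        return self.table.index[self.table["selected"]].tolist()

    def summary(self) -> dict:
        sel = self.table["selected"]
        return {
            "n_genes": len(self.table),
            "n_selected": int(sel.sum()),
            "mean_cv_r_selected": float(self.table.loc[sel, "pooled_r"].mean())
            if sel.any()
            else float("nan"),
        }


def select_genes(
    cv: CVResult,
    r2_min: float = R2_MIN_DEFAULT,
    q_max: float = Q_MAX_DEFAULT,
    require_positive_r: bool = True,
) -> list[str]:
    """Genes passing mean fold R^2 >= r2_min, q <= q_max (and pooled r > 0)."""
    t = cv.table
    mask = (t["mean_fold_r2"] >= r2_min) & (t["q"] <= q_max)
    if require_positive_r:
        mask &= t["pooled_r"] > 0
    return t.index[mask.fillna(False)].tolist()


def cross_validate(
    blood: ExpressionMatrix,
    lung: ExpressionMatrix,
    n_components: int = DEFAULT_N_COMPONENTS,
    k: int = 5,
    seed: int = 0,
    r2_min: float = R2_MIN_DEFAULT,
    q_max: float = Q_MAX_DEFAULT,
) -> CVResult:
    """k-fold cross-validated per-gene imputation accuracy.

    For every fold the PCA and gene models are refit on the remaining
    folds and applied to the held-out subjects. Reports, per gene, the
    fold-averaged r and r-squared, the correlation over pooled out-of-fold
    predictions with its p-value, the BH q across genes, and the selection
    flag.
    """
    if set(blood.sample_ids) != set(lung.sample_ids):
        raise ValueError("blood and lung matrices must share their sample IDs")
    lung = lung.select_samples(blood.sample_ids)
    subjects = blood.sample_ids
    n = len(subjects)
    folds = assign_folds(subjects, k=k, seed=seed)
    min_train = n - int(folds.value_counts().max())
    if min_train < n_components + 2:
        raise ValueError(
            f"smallest training split ({min_train}) cannot support "
            f"K={n_components}; use fewer components or fewer folds"
        )
    genes = lung.gene_ids
    g = len(genes)
    pooled_pred = np.full((g, n), np.nan)
    fold_r = np.full((g, k), np.nan)
    fold_mask = folds.to_numpy()
    obs = lung.values
    for fold in range(k):
        test = np.flatnonzero(fold_mask == fold)
        train = np.flatnonzero(fold_mask != fold)
        blood_tr = blood.select_samples([subjects[i] for i in train])
        lung_tr = lung.select_samples([subjects[i] for i in train])
        blood_te = blood.select_samples([subjects[i] for i in test])
        pca = fit_pca(blood_tr, n_components)
        models = train_gene_models(project_pca(pca, blood_tr), lung_tr)
        scores_te = project_pca(pca, blood_te)
        pred = models.intercepts[:, None] + models.coefficients @ scores_te.T
        pos = {gid: i for i, gid in enumerate(genes)}
        rows = np.array([pos[gid] for gid in models.gene_ids])
        pooled_pred[rows[:, None], test[None, :]] = pred
        fold_r[rows, fold] = row_correlations(obs[rows][:, test], pred)
    with np.errstate(invalid="ignore"):
        mean_fold_r = np.nanmean(fold_r, axis=1)
        mean_fold_r2 = np.nanmean(fold_r**2, axis=1)
    have_all = ~np.isnan(pooled_pred).any(axis=1)
    pooled_r = np.full(g, np.nan)
    pooled_r[have_all] = row_correlations(obs[have_all], pooled_pred[have_all])
    pooled_p = correlation_pvalues(pooled_r, n)
    q = bh_fdr(pooled_p)
    table = pd.DataFrame(
        {
            "mean_fold_r": mean_fold_r,
            "mean_fold_r2": mean_fold_r2,
            "pooled_r": pooled_r,
            "pooled_p": pooled_p,
            "q": q,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    selected = (
        (table["mean_fold_r2"] >= r2_min)
        & (table["q"] <= q_max)
        & (table["pooled_r"] > 0)
    )
    table["selected"] = selected.fillna(False)
    return CVResult(
        table=table,
        k=k,
        seed=seed,
        n=n,
        n_components=n_components,
        r2_min=r2_min,
        q_max=q_max,
    )
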