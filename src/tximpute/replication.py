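"""External replication of cross-validated imputation accuracy.

A gene's training accuracy (the pooled cross-validation correlation) is
compared with its accuracy in an independent paired dataset via Fisher's
z-transform: atanh(r) is approximately normal with variance 1/(n-3), so

    z = (atanh(r_train) - atanh(r_rep)) / sqrt(1/(n_train-3) + 1/(n_rep-3))

gives a two-tailed test of equal correlation. A gene replicates when its
accuracy does NOT differ significantly between cohorts (uncorrected
p > 0.05, strict) AND its replication-set correlation is at least 0.1
(inclusive). No multiplicity correction is applied to the replication
p-values: correcting them would make the no-difference condition easier
to satisfy, not harder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import row_correlations
from .crossval import CVResult, cross_validate
from .matrix import ExpressionMatrix, harmonize_genes
from .model import ImputationBundle, impute, train_bundle

R_MIN_DEFAULT = 0.1
P_MIN_DEFAULT = 0.05


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-tailed z-test for equality of two independent Pearson correlations."""
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 for the Fisher z transform")
        if n <= 3:
            raise ValueError("each sample size must exceed 3")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def replication_rule(
    p: float, r_rep: float, p_min: float = P_MIN_DEFAULT, r_min: float = R_MIN_DEFAULT
) -> bool:
    """Replicated iff p > p_min (strict) and r_rep >= r_min (inclusive)."""
    return bool(p > p_min and r_rep >= r_min)


def replicated_percentage(n_replicated: float, n_imputed: float) -> float:
    """Replicated transcripts as a percentage of reliably imputed transcripts."""
    if n_imputed <= 0:
        raise ValueError("n_imputed must be positive")
    return 100.0 * n_replicated / n_imputed


@dataclass
class ReplicationResult:
    """Per-gene replication table plus bookkeeping.

    ``table`` columns: r_train, n_train, r_rep, n_rep, z, p, replicated,
    indexed by gene_id (the CV-selected genes present in the replication
    data). ``n_missing`` counts selected genes absent from the replication
    lung matrix.
    """

    table: pd.DataFrame
    n_missing: int = 0

    def summary(self) -> dict:
        n_eval = len(self.table)
        n_rep = int(self.table["replicated"].sum())
        return {
            "n_evaluated": n_eval,
            "n_missing": self.n_missing,
            "n_replicated": n_rep,
            "pct_replicated": replicated_percentage(n_rep, n_eval) if n_eval else float("nan"),
            "mean_r_rep": float(self.table["r_rep"].mean()) if n_eval else float("nan"),
        }


def evaluate_replication(
    cv: CVResult,
    bundle: ImputationBundle,
    rep_blood: ExpressionMatrix,
    rep_lung: ExpressionMatrix,
    r_min: float = R_MIN_DEFAULT,
    p_min: float = P_MIN_DEFAULT,
) -> ReplicationResult:
    """Test whether CV-selected genes keep their accuracy in a new cohort.

    Imputes replication-set lung expression from replication blood, then
    per selected gene correlates imputed with observed lung values and
    compares that correlation with the training (pooled CV) correlation by
    Fisher z. Selected genes missing from the replication lung matrix are
    excluded and counted.
    """
    if set(rep_blood.sample_ids) != set(rep_lung.sample_ids):
        raise ValueError("replication blood and lung must share sample IDs")
    rep_lung = rep_lung.select_samples(rep_blood.sample_ids)
    n_rep = rep_blood.n_samples
    if n_rep <= 3:
        raise ValueError("replication cohort must have more than 3 subjects")
    selected = cv.selected_genes
    imputed = impute(bundle, rep_blood)
    available = set(imputed.gene_ids) & set(rep_lung.gene_ids)
    genes = [g for g in selected if g in available]
    n_missing = len(selected) - len(genes)
    r_rep = row_correlations(
        imputed.data.loc[genes].to_numpy(dtype=float),
        rep_lung.data.loc[genes].to_numpy(dtype=float),
    )
    r_train = cv.table.loc[genes, "pooled_r"].to_numpy()
    # vectorized Fisher z; clamp to the open interval so atanh stays finite
    eps = 1e-12
    rt = np.clip(r_train, -1 + eps, 1 - eps)
    rr = np.clip(np.nan_to_num(r_rep), -1 + eps, 1 - eps)
    se = np.sqrt(1.0 / (cv.n - 3) + 1.0 / (n_rep - 3))
    z = (np.arctanh(rt) - np.arctanh(rr)) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    replicated = (p > p_min) & (r_rep >= r_min)
    table = pd.DataFrame(
        {
            "r_train": r_train,
            "n_train": cv.n,
            "r_rep": r_rep,
            "n_rep": n_rep,
            "z": z,
            "p": p,
            "replicated": np.where(np.isnan(r_rep), False, replicated),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return ReplicationResult(table=table, n_missing=n_missing)


def blood_lung_concordance(
    blood: ExpressionMatrix, lung: ExpressionMatrix
) -> pd.DataFrame:
    """Per-gene correlation of blood vs lung expression across paired subjects.

    The baseline the imputation model is meant to beat: how well does a
    gene's own blood level track its lung level? Genes constant in either
    tissue are dropped; their count is recorded in ``attrs['n_flagged']``.
    """
    if set(blood.sample_ids) != set(lung.sample_ids):
        raise ValueError("blood and lung must share sample IDs")
    lung = lung.select_samples(blood.sample_ids)
    blood_h, lung_h = harmonize_genes(blood, lung)
    r = row_correlations(blood_h.values, lung_h.values)
    out = pd.DataFrame(
        {"r": r}, index=pd.Index(blood_h.gene_ids, name="gene_id")
    )
    n_flagged = int(np.isnan(r).sum())
    out = out.dropna()
    out.attrs["n_flagged"] = n_flagged
    return out


def component_sweep(
    blood: ExpressionMatrix,
    lung: ExpressionMatrix,
    component_grid=(5, 10, 20, 40),
    k: int = 5,
    seed: int = 0,
    rep_blood: ExpressionMatrix | None = None,
    rep_lung: ExpressionMatrix | None = None,
) -> pd.DataFrame:
    """Compare imputation models across numbers of principal components.

    For each K: run cross-validation, count reliably imputed genes and
    their mean CV accuracy, and — when a replication pair is supplied —
    evaluate replication and report the replicated count, percentage, and
    mean validation accuracy. One row per K.
    """
    rows = []
    for n_components in component_grid:
        cv = cross_validate(blood, lung, n_components=n_components, k=k, seed=seed)
        row = {
            "n_pcs": n_components,
            "n_imputed": len(cv.selected_genes),
            "mean_cv_accuracy": cv.summary()["mean_cv_r_selected"],
        }
        if rep_blood is not None and rep_lung is not None:
            bundle = train_bundle(blood, lung, n_components=n_components)
            rep = evaluate_replication(cv, bundle, rep_blood, rep_lung)
            s = rep.summary()
            row.update(
                {
                    "mean_validation_accuracy": s["mean_r_rep"],
                    "n_replicated": s["n_replicated"],
                    "pct_replicated": s["pct_replicated"],
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
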