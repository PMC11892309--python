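"""The core imputation model: principal-component regression across tissues.

Blood expression is standardized gene-wise and decomposed by PCA; each
target-tissue (lung) gene is then regressed by ordinary least squares on
the top K principal-component scores:

    Y_g = beta_0 + beta_1 X_1 + ... + beta_K X_K + eps

where X_k is the k-th blood PC score of a subject. A trained bundle stores
the PCA parameters (per-gene means/SDs and rotation) together with the
per-gene coefficients, so it can be applied to blood profiles from a new
cohort after gene harmonization. OLS is used rather than a penalized fit:
with K ~ tens of orthogonal predictors and hundreds of subjects the
least-squares problem is well conditioned, and penalization has not been
observed to improve this model class.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

FORMAT_VERSION = "1.0"
DEFAULT_N_COMPONENTS = 20
MIN_GENE_COVERAGE = 0.5


@dataclass
class PCAModel:
    """Standardization parameters and top-K rotation of the blood PCA.

    ``rotation`` is genes x K with orthonormal columns; the sign of each
    component is fixed so its largest-magnitude loading is positive, making
    trained models reproducible across platforms.
    """

    gene_ids: list[str]
    gene_means: np.ndarray
    gene_sds: np.ndarray
    rotation: np.ndarray
    n_components: int
    explained_variance: np.ndarray | None = None
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rotation.shape != (len(self.gene_ids), self.n_components):
            raise ValueError("rotation shape does not match gene list / K")
        if (self.gene_sds <= 0).any():
            raise ValueError("gene SDs must all be positive")
        gram = self.rotation.T @ self.rotation
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ValueError("rotation columns are not orthonormal")


@dataclass
class GeneModelSet:
    """Per-gene OLS coefficients for the modeled target-tissue genes."""

    gene_ids: list[str]
    intercepts: np.ndarray  # (G,)
    coefficients: np.ndarray  # (G, K)
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.coefficients.shape[1]

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class ImputationBundle:
    """Trained artifact: blood PCA + per-gene regressions + metadata."""

    pca: PCAModel
    models: GeneModelSet
    training_n: int
    created: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    format_version: str = FORMAT_VERSION

    def __post_init__(self) -> None:
        if self.models.n_components != self.pca.n_components:
            raise ValueError("gene models and PCA disagree on K")
        if self.training_n < self.pca.n_components + 2:
            raise ValueError("training_n must be at least K + 2")

    @property
    def n_components(self) -> int:
        return self.pca.n_components


def fit_pca(blood: ExpressionMatrix, n_components: int = DEFAULT_N_COMPONENTS) -> PCAModel:
    """Standardized PCA of blood expression, samples as observations.

    Each gene is centered by its mean and scaled by its SD (ddof=1);
    the rotation holds the top-K right singular vectors of the resulting
    samples x genes matrix. Zero-variance genes are dropped with a warning
    and recorded on the model. K defaults to 20 components.
    """
    if blood.unit not in ("log2cpm", "normalized"):
        raise ValueError(
            f"PCA expects log2cpm or normalized input, got unit {blood.unit!r}"
        )
    x = blood.values.T  # samples x genes
    n = x.shape[0]
    sds = x.std(axis=0, ddof=1)
    dropped = [g for g, s in zip(blood.gene_ids, sds) if s == 0]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance gene(s) before PCA", stacklevel=2
        )
    keep = sds > 0
    gene_ids = [g for g, k in zip(blood.gene_ids, keep) if k]
    x = x[:, keep]
    max_k = min(n - 1, x.shape[1])
    if not 1 <= n_components <= max_k:
        raise ValueError(
            f"n_components={n_components} out of range [1, {max_k}] "
            f"for {n} samples x {x.shape[1]} genes"
        )
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    xs = (x - means) / sds
    _, svals, vt = np.linalg.svd(xs, full_matrices=False)
    rotation = vt[:n_components].T.copy()
    # deterministic sign: largest-magnitude loading of each component positive
    for k in range(n_components):
        i = int(np.argmax(np.abs(rotation[:, k])))
        if rotation[i, k] < 0:
            rotation[:, k] *= -1
    return PCAModel(
        gene_ids=gene_ids,
        gene_means=means,
        gene_sds=sds,
        rotation=rotation,
        n_components=n_components,
        explained_variance=svals[:n_components] ** 2 / (n - 1),
        dropped_genes=dropped,
    )


def project_pca(model: PCAModel, blood: ExpressionMatrix) -> np.ndarray:
    """Project blood samples onto the model's components (samples x K).

    Standardization always uses the *model's* stored means and SDs. Genes
    absent from the input contribute 0 after standardization (i.e. sit at
    the training mean); coverage below 50% of the model's genes is refused.
    """
    present = [g for g in model.gene_ids if g in set(blood.gene_ids)]
    coverage = len(present) / len(model.gene_ids)
    if coverage < MIN_GENE_COVERAGE:
        raise ValueError(
            f"blood matrix covers only {coverage:.1%} of the model's "
            f"{len(model.gene_ids)} genes (minimum {MIN_GENE_COVERAGE:.0%})"
        )
    pos = {g: i for i, g in enumerate(model.gene_ids)}
    xs = np.zeros((blood.n_samples, len(model.gene_ids)))
    sub = blood.data.loc[present].to_numpy(dtype=float).T  # samples x present
    idx = [pos[g] for g in present]
    xs[:, idx] = (sub - model.gene_means[idx]) / model.gene_sds[idx]
    return xs @ model.rotation


def train_gene_models(scores: np.ndarray, lung: ExpressionMatrix) -> GeneModelSet:
    """OLS fit of every target-tissue gene on the PC scores (plus intercept).

    Rows of *scores* must align with the columns of *lung*. Genes with zero
    variance carry no fittable signal and are skipped with a recorded
    reason. A rank-deficient design (e.g. duplicated score columns) is an
    error rather than a silent pseudo-inverse fit.
    """
    n, k = scores.shape
    if lung.n_samples != n:
        raise ValueError(
            f"scores have {n} rows but lung matrix has {lung.n_samples} samples"
        )
    if n < k + 2:
        raise ValueError(f"need at least K + 2 = {k + 2} samples, got {n}")
    design = np.column_stack([np.ones(n), scores])
    if np.linalg.matrix_rank(design) < k + 1:
        raise ValueError("rank-deficient design matrix (collinear score columns)")
    y = lung.values  # genes x samples
    sds = y.std(axis=1, ddof=1)
    skipped = {g: "zero variance" for g, s in zip(lung.gene_ids, sds) if s == 0}
    keep = sds > 0
    gene_ids = [g for g, m in zip(lung.gene_ids, keep) if m]
    coef, *_ = np.linalg.lstsq(design, y[keep].T, rcond=None)
    return GeneModelSet(
        gene_ids=gene_ids,
        intercepts=coef[0].copy(),
        coefficients=coef[1:].T.copy(),
        skipped=skipped,
    )


def train_bundle(
    blood: ExpressionMatrix,
    lung: ExpressionMatrix,
    n_components: int = DEFAULT_N_COMPONENTS,
) -> ImputationBundle:
    """Train the full cross-tissue model from paired blood/lung matrices.

    Samples must be paired subject-for-subject; the lung matrix is aligned
    to the blood sample order before fitting.
    """
    blood_set, lung_set = set(blood.sample_ids), set(lung.sample_ids)
    if blood_set != lung_set:
        missing = sorted(blood_set ^ lung_set)
        raise ValueError(f"unpaired samples between blood and lung: {missing[:10]}")
    lung = lung.select_samples(blood.sample_ids)
    pca = fit_pca(blood, n_components)
    scores = project_pca(pca, blood)
    models = train_gene_models(scores, lung)
    return ImputationBundle(pca=pca, models=models, training_n=blood.n_samples)


def impute(bundle: ImputationBundle, blood: ExpressionMatrix) -> ExpressionMatrix:
    """Impute target-tissue expression for new blood samples.

    Output is modeled genes x input samples with unit ``imputed``.
    """
    scores = project_pca(bundle.pca, blood)
    values = bundle.models.intercepts[:, None] + bundle.models.coefficients @ scores.T
    df = pd.DataFrame(values, index=bundle.models.gene_ids, columns=blood.sample_ids)
    df.index.name = "gene_id"
    return ExpressionMatrix(df, "imputed")


# -- serialization -------------------------------------------------------------
#
# A bundle directory holds three inspectable text files:
#   meta.json   format version, K, training_n, created, dropped/skipped genes
#   pca.tsv     gene_id, mean, sd, rot_1..rot_K
#   models.tsv  gene_id, beta0, beta_1..beta_K

def save_bundle(bundle: ImputationBundle, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": bundle.format_version,
        "n_components": bundle.n_components,
        "training_n": bundle.training_n,
        "created": bundle.created,
        "dropped_genes": bundle.pca.dropped_genes,
        "skipped_genes": bundle.models.skipped,
        "explained_variance": (
            None
            if bundle.pca.explained_variance is None
            else bundle.pca.explained_variance.tolist()
        ),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    k = bundle.n_components
    pca_df = pd.DataFrame(
        {
            "gene_id": bundle.pca.gene_ids,
            "mean": bundle.pca.gene_means,
            "sd": bundle.pca.gene_sds,
            **{f"rot_{i + 1}": bundle.pca.rotation[:, i] for i in range(k)},
        }
    )
    pca_df.to_csv(path / "pca.tsv", sep="\t", index=False, float_format="%.17g")
    model_df = pd.DataFrame(
        {
            "gene_id": bundle.models.gene_ids,
            "beta0": bundle.models.intercepts,
            **{f"beta_{i + 1}": bundle.models.coefficients[:, i] for i in range(k)},
        }
    )
    model_df.to_csv(path / "models.tsv", sep="\t", index=False, float_format="%.17g")


def load_bundle(path) -> ImputationBundle:
    path = Path(path)
    try:
        meta = json.loads((path / "meta.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read bundle metadata at {path}: {exc}") from exc
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"bundle format version {version!r} does not match "
            f"supported version {FORMAT_VERSION!r}"
        )
    k = int(meta["n_components"])
    pca_df = pd.read_csv(path / "pca.tsv", sep="\t")
    model_df = pd.read_csv(path / "models.tsv", sep="\t")
    expected_pca = ["gene_id", "mean", "sd"] + [f"rot_{i + 1}" for i in range(k)]
    expected_models = ["gene_id", "beta0"] + [f"beta_{i + 1}" for i in range(k)]
    if list(pca_df.columns) != expected_pca or list(model_df.columns) != expected_models:
        raise ValueError(f"bundle files at {path} are truncated or malformed")
    ev = meta.get("explained_variance")
    pca = PCAModel(
        gene_ids=pca_df["gene_id"].astype(str).tolist(),
        gene_means=pca_df["mean"].to_numpy(),
        gene_sds=pca_df["sd"].to_numpy(),
        rotation=pca_df[[f"rot_{i + 1}" for i in range(k)]].to_numpy(),
        n_components=k,
        explained_variance=None if ev is None else np.asarray(ev),
        dropped_genes=list(meta.get("dropped_genes", [])),
    )
    models = GeneModelSet(
        gene_ids=model_df["gene_id"].astype(str).tolist(),
        intercepts=model_df["beta0"].to_numpy(),
        coefficients=model_df[[f"beta_{i + 1}" for i in range(k)]].to_numpy(),
        skipped=dict(meta.get("skipped_genes", {})),
    )
    return ImputationBundle(
        pca=pca,
        models=models,
        training_n=int(meta["training_n"]),
        created=str(meta.get("created", "")),
        format_version=version,
    )
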