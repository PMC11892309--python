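"""Synthetic paired-tissue expression data with known ground truth.

The paired generator is a Gaussian latent-factor model on the normalized
(log-like) expression scale: subjects carry q standard-normal latent
factors; every blood gene is a unit-norm loading combination of the
factors plus Gaussian noise; every lung gene splits its unit variance
between a factor combination (fraction f, its *imputability*) and
independent noise (fraction 1 - f). Because blood observes the factors
through many noisy genes and lung genes draw exactly fraction f of their
variance from those factors, sqrt(f) is an analytic ceiling on the
achievable imputation correlation — which makes f the ground truth every
accuracy claim is checked against.

Counts for the normalization stages are simulated separately as
negative-binomial draws with log-normal gene means and per-sample library
size multipliers.

Case-control cohorts embed disease effects through one of two routes:
``shared_factor`` shifts a latent factor that both tissues load on, so a
mixed and attenuated trace of the effect reaches blood and imputation can
recover the lung effect; ``lung_private`` adds the effect to lung
residuals only, which no blood-based predictor can see. The contrast
between the two routes is what separates a working cross-tissue pipeline
from one that merely relabels blood signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


@dataclass
class SimTruth:
    """Ground truth of a paired simulation.

    ``lung_table`` has one row per lung gene: shared_fraction (f) and
    true_log2fc (0 for null genes). Loadings are genes x factors.
    """

    lung_table: pd.DataFrame
    blood_loadings: np.ndarray
    lung_loadings: np.ndarray
    n_factors: int
    noise_sd: float
    seed: int
    factors: np.ndarray | None = None  # subjects x q latent factor scores


@dataclass
class CaseControlSim:
    """A simulated case-control cohort plus an independent training pair.

    ``blood``/``lung``/``metadata`` describe the cohort (cases +
    controls); ``train_blood``/``train_lung`` are paired samples from the
    same generative model with no disease shift, for model training.
    """

    blood: ExpressionMatrix
    lung: ExpressionMatrix
    metadata: pd.DataFrame
    truth: SimTruth
    train_blood: ExpressionMatrix
    train_lung: ExpressionMatrix


def _as_fraction_array(shared_fractions, n_lung_genes: int) -> np.ndarray:
    f = np.broadcast_to(np.asarray(shared_fractions, dtype=float), (n_lung_genes,)).copy()
    if ((f < 0) | (f > 1)).any():
        raise ValueError("shared fractions must lie in [0, 1]")
    return f


def _row_normalize(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return x / norms


def _matrix(values, prefix_rows, prefix_cols, unit="normalized") -> ExpressionMatrix:
    df = pd.DataFrame(
        values,
        index=pd.Index(prefix_rows, name="gene_id"),
        columns=prefix_cols,
    )
    return ExpressionMatrix(df, unit)


def _gene_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:04d}" for i in range(n)]


def simulate_paired(
    n_subjects: int,
    n_blood_genes: int = 1000,
    n_lung_genes: int = 500,
    n_factors: int = 10,
    shared_fractions=0.3,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SimTruth]:
    """Paired blood/lung matrices with per-gene shared-variance fractions.

    Lung genes have population variance exactly 1, of which fraction f
    flows through factors shared with blood. ``noise_sd`` is the blood
    residual SD on top of the unit-variance blood factor signal.
    """
    if n_subjects < n_factors + 2:
        raise ValueError("need at least n_factors + 2 subjects")
    f = _as_fraction_array(shared_fractions, n_lung_genes)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_subjects, n_factors))
    blood_load = _row_normalize(rng.standard_normal((n_blood_genes, n_factors)))
    lung_load = _row_normalize(rng.standard_normal((n_lung_genes, n_factors)))
    blood = blood_load @ z.T + noise_sd * rng.standard_normal((n_blood_genes, n_subjects))
    shared = lung_load @ z.T
    lung = np.sqrt(f)[:, None] * shared + np.sqrt(1 - f)[:, None] * rng.standard_normal(
        (n_lung_genes, n_subjects)
    )
    subjects = [f"S{i + 1:04d}" for i in range(n_subjects)]
    truth = SimTruth(
        lung_table=pd.DataFrame(
            {"shared_fraction": f, "true_log2fc": np.zeros(n_lung_genes)},
            index=pd.Index(_gene_ids("LG", n_lung_genes), name="gene_id"),
        ),
        blood_loadings=blood_load,
        lung_loadings=lung_load,
        n_factors=n_factors,
        noise_sd=noise_sd,
        seed=seed,
        factors=z,
    )
    return (
        _matrix(blood, _gene_ids("BG", n_blood_genes), subjects),
        _matrix(lung, _gene_ids("LG", n_lung_genes), subjects),
        truth,
    )


def simulate_counts(
    n_genes: int,
    n_samples: int,
    mean_log_expr: tuple[float, float] = (2.0, 1.2),
    dispersion: float = 0.1,
    lib_size_range: tuple[float, float] = (0.5, 1.5),
    seed: int = 0,
) -> ExpressionMatrix:
    """Negative-binomial count matrix for exercising normalization stages.

    Gene base means are log-normal with the given (meanlog, sdlog) on the
    natural-log scale; sample library-size multipliers are uniform over
    ``lib_size_range``; the NB variance is mean + dispersion * mean^2.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(mean_log_expr[0], mean_log_expr[1], size=n_genes)
    lib = rng.uniform(lib_size_range[0], lib_size_range[1], size=n_samples)
    mean = mu[:, None] * lib[None, :]
    size = 1.0 / dispersion
    p = size / (size + mean)
    counts = rng.negative_binomial(size, p)
    return _matrix(
        counts.astype(float),
        _gene_ids("G", n_genes),
        [f"S{j + 1:04d}" for j in range(n_samples)],
        unit="counts",
    )


def simulate_case_control(
    n_cases: int,
    n_controls: int,
    n_blood_genes: int = 1000,
    n_lung_genes: int = 500,
    n_factors: int = 10,
    shared_fractions=0.5,
    noise_sd: float = 0.5,
    effect_genes=None,
    effect_route: str = "shared_factor",
    factor_shift: float = 2.0,
    n_train_pairs: int = 300,
    age_case_shift: float = 0.0,
    seed: int = 0,
) -> CaseControlSim:
    """Case-control cohort with embedded lung effects plus a training pair.

    ``effect_genes`` maps lung gene IDs (``LG0001`` ...) to their true
    case-minus-control log2 fold change; an integer n means the first n
    lung genes at log2fc 0.5. Route ``shared_factor`` wires the effects
    through a latent factor both tissues load on (cases have that factor
    shifted by ``factor_shift``); route ``lung_private`` adds them to lung
    residuals only. ``age_case_shift`` optionally confounds age with
    status (added to case ages) for sensitivity checks; it defaults to 0
    so covariates are independent of status.
    """
    if effect_route not in ("shared_factor", "lung_private"):
        raise ValueError(f"unknown effect_route {effect_route!r}")
    lung_ids = _gene_ids("LG", n_lung_genes)
    if effect_genes is None:
        effect_genes = {}
    elif isinstance(effect_genes, int):
        effect_genes = {lung_ids[i]: 0.5 for i in range(effect_genes)}
    unknown = set(effect_genes) - set(lung_ids)
    if unknown:
        raise ValueError(f"effect genes not in the lung gene set: {sorted(unknown)[:5]}")
    f = _as_fraction_array(shared_fractions, n_lung_genes)
    rng = np.random.default_rng(seed)

    # factor q-1 is the disease-linked factor; blood genes load on it
    # generically, lung genes only if they carry a shared-route effect
    blood_load = _row_normalize(rng.standard_normal((n_blood_genes, n_factors)))
    lung_raw = rng.standard_normal((n_lung_genes, n_factors))
    lung_raw[:, -1] = 0.0
    lung_load = _row_normalize(lung_raw)
    deltas = np.zeros(n_lung_genes)
    for gid, delta in effect_genes.items():
        deltas[lung_ids.index(gid)] = float(delta)
    if effect_route == "shared_factor":
        idx = np.flatnonzero(deltas != 0)
        with np.errstate(divide="ignore"):
            d_load = deltas[idx] / (np.sqrt(f[idx]) * factor_shift)
        if (np.abs(d_load) >= 1).any() or (f[idx] == 0).any():
            raise ValueError(
                "effect too large for its shared fraction: need "
                "|log2fc| < sqrt(f) * factor_shift"
            )
        lung_load[idx] *= np.sqrt(1 - d_load**2)[:, None]
        lung_load[idx, -1] = d_load

    def _draw_pair(z, n):
        blood = blood_load @ z.T + noise_sd * rng.standard_normal((n_blood_genes, n))
        lung = np.sqrt(f)[:, None] * (lung_load @ z.T) + np.sqrt(1 - f)[
            :, None
        ] * rng.standard_normal((n_lung_genes, n))
        return blood, lung

    z_train = rng.standard_normal((n_train_pairs, n_factors))
    blood_train, lung_train = _draw_pair(z_train, n_train_pairs)

    n = n_cases + n_controls
    case = np.zeros(n)
    case[:n_cases] = 1.0
    z = rng.standard_normal((n, n_factors))
    if effect_route == "shared_factor":
        z[:, -1] += factor_shift * case
    blood, lung = _draw_pair(z, n)
    if effect_route == "lung_private":
        lung += deltas[:, None] * case[None, :]

    subjects = [f"C{i + 1:05d}" for i in range(n)]
    order = rng.permutation(n)  # shuffle so cases are not a contiguous block
    blood, lung, case, z = blood[:, order], lung[:, order], case[order], z[order]
    status = np.where(case == 1, "case", "control")
    age = rng.uniform(45, 80, size=n) + age_case_shift * case
    metadata = pd.DataFrame(
        {
            "sample_id": subjects,
            "subject_id": subjects,
            "age": age,
            "sex": rng.choice(["male", "female"], size=n),
            "batch": rng.choice(["B1", "B2"], size=n),
            "disease_status": status,
            "fev1_fvc": np.where(
                case == 1, rng.uniform(0.40, 0.695, size=n), rng.uniform(0.705, 0.90, size=n)
            ),
            "pct_neut": np.clip(rng.normal(60, 8, size=n), 0, 100),
            "pct_lymph": np.clip(rng.normal(30, 7, size=n), 0, 100),
            "pct_mono": np.clip(rng.normal(8, 2, size=n), 0, 100),
            "pct_eos": np.clip(rng.normal(3, 1.5, size=n), 0, 100),
        }
    ).set_index("sample_id", drop=False)
    train_ids = [f"T{i + 1:05d}" for i in range(n_train_pairs)]
    truth = SimTruth(
        lung_table=pd.DataFrame(
            {"shared_fraction": f, "true_log2fc": deltas},
            index=pd.Index(lung_ids, name="gene_id"),
        ),
        blood_loadings=blood_load,
        lung_loadings=lung_load,
        n_factors=n_factors,
        noise_sd=noise_sd,
        seed=seed,
        factors=z,
    )
    blood_ids = _gene_ids("BG", n_blood_genes)
    return CaseControlSim(
        blood=_matrix(blood, blood_ids, subjects),
        lung=_matrix(lung, lung_ids, subjects),
        metadata=metadata,
        truth=truth,
        train_blood=_matrix(blood_train, blood_ids, train_ids),
        train_lung=_matrix(lung_train, lung_ids, train_ids),
    )
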