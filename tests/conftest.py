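import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import tximpute as tx

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_matrix() -> tx.ExpressionMatrix:
    """3 genes x 2 samples, counts."""
    df = pd.DataFrame(
        [[1.0, 4.0], [1.0, 1.0], [2.0, 6.0]],
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=["s1", "s2"],
    )
    return tx.ExpressionMatrix(df, "counts")


@pytest.fixture(scope="session")
def paired_sim():
    """Paired blood/lung data with graded imputability, shared by tests."""
    fractions = np.repeat([0.0, 0.05, 0.2, 0.5], 50)
    blood, lung, truth = tx.simulate_paired(
        200, 400, 200, n_factors=8, shared_fractions=fractions, noise_sd=0.5, seed=101
    )
    return blood, lung, truth


def make_matrix(values, unit="normalized", gene_prefix="g", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=pd.Index([f"{gene_prefix}{i + 1}" for i in range(values.shape[0])], name="gene_id"),
        columns=[f"{sample_prefix}{j + 1}" for j in range(values.shape[1])],
    )
    return tx.ExpressionMatrix(df, unit)
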