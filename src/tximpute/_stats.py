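"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats


def row_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of matching rows of two (G x n) matrices.

    Rows where either side is constant get NaN.
    """
    constant = (a.max(axis=1) == a.min(axis=1)) | (b.max(axis=1) == b.min(axis=1))
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((den > 0) & ~constant, num / den, np.nan)
    return np.clip(r, -1.0, 1.0)


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via t = r sqrt((n-2)/(1-r^2)) on n-2 df."""
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.where(np.isnan(r), np.nan, p)
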