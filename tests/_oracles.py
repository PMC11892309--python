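"""Deliberately naive, loop-based reference implementations.

These transcribe each statistical definition step by step, independently
of the vectorized library code, and exist only to cross-check it.
"""

from __future__ import annotations

import math

import numpy as np


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg q-values straight from the step-up definition:

    q_(i) = min_{j >= i} min(1, m * p_(j) / j) over the sorted p-values.
    """
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, m * p[i] / rank))
        q_sorted[rank - 1] = running
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return np.array(q)


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(X'X)^-1 X'y with an explicit intercept column."""
    design = np.column_stack([np.ones(len(y)), x])
    return np.linalg.solve(design.T @ design, design.T @ y)


def _average_ranks(values) -> list[float]:
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_naive(counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Step-by-step trimmed-mean-of-M-values scaling factors.

    Reference = sample whose upper quartile of library-scaled counts (over
    genes expressed somewhere) is closest to the mean upper quartile; per
    sample, a doubly trimmed, precision-weighted mean of M-values against
    the reference; factors rescaled to geometric mean one.
    """
    counts = np.asarray(counts, dtype=float)
    lib = [sum(counts[:, j]) for j in range(counts.shape[1])]
    expressed = [g for g in range(counts.shape[0]) if any(counts[g, :] > 0)]
    counts = counts[expressed, :]
    f75 = [
        float(np.quantile([counts[g, j] / lib[j] for g in range(counts.shape[0])], 0.75))
        for j in range(counts.shape[1])
    ]
    mean_f75 = sum(f75) / len(f75)
    ref = min(range(len(f75)), key=lambda j: abs(f75[j] - mean_f75))
    log_factors = []
    for j in range(counts.shape[1]):
        m_vals, a_vals, weights = [], [], []
        for g in range(counts.shape[0]):
            o, r = counts[g, j], counts[g, ref]
            if o > 0 and r > 0:
                po, pr = o / lib[j], r / lib[ref]
                m_vals.append(math.log2(po / pr))
                a_vals.append(0.5 * math.log2(po * pr))
                weights.append(
                    1.0
                    / ((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
                )
        if not m_vals or max(abs(m) for m in m_vals) < 1e-10:
            log_factors.append(0.0)
            continue
        n = len(m_vals)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = _average_ranks(m_vals)
        rank_a = _average_ranks(a_vals)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += weights[i] * m_vals[i]
                den += weights[i]
        f = num / den if den else 0.0
        log_factors.append(0.0 if abs(f) < 1e-6 else f)
    mean_log = sum(log_factors) / len(log_factors)
    return np.array([2.0 ** (f - mean_log) for f in log_factors])
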