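"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written from the definition of the operation, using a
different code path (plain python sorting, exhaustive enumeration,
micro-unit subdivision) from the vectorized implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def constant_genes_oracle(gene_ids, values, n_bins=100, percent=10.0):
    """Sort by mean -> contiguous equal bins -> per-bin lowest-SD pick."""
    gene_ids = list(gene_ids)
    values = np.asarray(values, dtype=float)
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    order = sorted(range(len(gene_ids)), key=lambda i: (means[i], gene_ids[i]))
    n = len(order)
    base, rem = divmod(n, n_bins)
    picked = set()
    pos = 0
    for b in range(n_bins):
        size = base + (1 if b < rem else 0)
        grp = order[pos : pos + size]
        pos += size
        take = math.ceil(percent / 100.0 * size)
        grp = sorted(grp, key=lambda i: (sds[i], gene_ids[i]))
        picked.update(gene_ids[i] for i in grp[:take])
    return picked


def ols_oracle(x, y):
    """Closed-form simple linear regression with intercept."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    intercept = y.mean() - slope * x.mean()
    return slope, intercept


def resample_oracle(values, n_bins):
    """Exact fractional-coverage body resampling via micro-unit subdivision.

    Each base is split into n_bins micro-units so every resampling bin
    boundary falls on a micro-unit boundary; bin means are then plain
    averages of micro-units.
    """
    values = np.asarray(values, dtype=float)
    micro = np.repeat(values, n_bins)
    return micro.reshape(n_bins, -1).mean(axis=1)


def quantile_normalize_oracle(matrix):
    """Classic rank-wise quantile normalization, column by column."""
    matrix = np.asarray(matrix, dtype=float)
    ranks = np.argsort(np.argsort(matrix, axis=0, kind="stable"), axis=0, kind="stable")
    sorted_cols = np.sort(matrix, axis=0)
    row_means = sorted_cols.mean(axis=1)
    return row_means[ranks]


def pairwise_percent_diff_oracle(areas):
    """Mean over unordered pairs of 100*|Ai-Aj|/((Ai+Aj)/2)."""
    diffs = []
    for a, b in itertools.combinations(areas, 2):
        denom = (a + b) / 2.0
        diffs.append(0.0 if denom == 0 else 100.0 * abs(a - b) / denom)
    return float(np.mean(diffs))


def kmeans_1d_oracle(values):
    """Optimal 1-D 3-means by exhausting contiguous partitions of sorted data.

    Returns cluster sizes from the lowest-center cluster up.  (The 1-D
    k-means optimum is always contiguous in sorted order.)
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    best = None
    for i in range(1, n - 1):
        for j in range(i + 1, n):
            parts = (v[:i], v[i:j], v[j:])
            sse = sum(((p - p.mean()) ** 2).sum() for p in parts)
            if best is None or sse < best[0]:
                best = (sse, (i, j - i, n - j))
    return best[1]
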