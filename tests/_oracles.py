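"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the package's vectorised code
paths: plain Python loops over voxels, pairwise comparisons, and full
enumerations, so the tests compare two independent routes.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_lung_max(spect: np.ndarray, mask: np.ndarray) -> float:
    best = None
    for idx in np.ndindex(spect.shape):
        if mask[idx]:
            v = float(spect[idx])
            if best is None or v > best:
                best = v
    assert best is not None
    return best


def brute_force_defect_fraction(
    spect: np.ndarray, left: np.ndarray, right: np.ndarray, threshold_percent: int
) -> float:
    """Strictly-below-threshold voxel count over both lungs, per-lung max."""
    n_defect = 0
    n_total = 0
    for mask in (left, right):
        m = brute_force_lung_max(spect, mask)
        thr = threshold_percent / 100.0 * m
        for idx in np.ndindex(spect.shape):
            if mask[idx]:
                n_total += 1
                if float(spect[idx]) < thr:
                    n_defect += 1
    return n_defect / n_total


def brute_force_decile_bins(spect: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-voxel binning into ten equal intervals of [0, per-lung max]."""
    m = brute_force_lung_max(spect, mask)
    counts = np.zeros(10, dtype=int)
    n = 0
    for idx in np.ndindex(spect.shape):
        if mask[idx]:
            n += 1
            v = float(spect[idx])
            k = int(v * 10.0 / m)
            if k > 9:
                k = 9
            counts[k] += 1
    return counts / n


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean over all case-control pairs of 1[case > control] + 0.5[equal]."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    total = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                total += 1.0
            elif x == y:
                total += 0.5
    return total / (len(pos) * len(neg))


def mann_whitney_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of label
    assignments (no ties assumed)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_stat(x, y):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

    u_obs = u_stat(a, b)
    mean_u = n1 * len(b) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    idx = range(len(pooled))
    for comb_ in combinations(idx, n1):
        x = pooled[list(comb_)]
        y = np.delete(pooled, list(comb_))
        if abs(u_stat(x, y) - mean_u) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def rank_then_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Definitional Spearman: average ranks, then Pearson correlation."""

    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        sorted_v = v[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(np.asarray(x, float)), avg_ranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
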