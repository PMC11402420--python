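"""Independent brute-force oracles for texture statistics and ranking AUC.

Everything here is deliberately naive — explicit enumeration of voxel
pairs, flood-fill zone discovery, exhaustive pair counting — so it shares
no code path with the vectorized implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_glcm(bins: np.ndarray, roi: np.ndarray, directions, n_bins: int,
               distance: int = 1) -> np.ndarray:
    """Symmetric co-occurrence counts by explicit ordered-pair enumeration."""
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)
    idx_iter = itertools.product(*[range(s) for s in bins.shape])
    for idx in idx_iter:
        if not roi[idx]:
            continue
        for off in directions:
            for sign in (1, -1):
                nb = tuple(i + sign * o * distance for i, o in zip(idx, off))
                if any(j < 0 or j >= s for j, s in zip(nb, bins.shape)):
                    continue
                if not roi[nb]:
                    continue
                counts[bins[idx] - 1, bins[nb] - 1] += 1
    return counts


def brute_glcm_sum_variance(p: np.ndarray) -> float:
    """Sum variance as the raw double sum over (i, j) pairs."""
    n = p.shape[0]
    sa = sum(
        (i + j) * p[i - 1, j - 1]
        for i in range(1, n + 1) for j in range(1, n + 1)
    )
    return sum(
        (i + j - sa) ** 2 * p[i - 1, j - 1]
        for i in range(1, n + 1) for j in range(1, n + 1)
    )


def brute_glcm_cluster_shade(p: np.ndarray) -> float:
    n = p.shape[0]
    mu_x = sum(i * p[i - 1, j - 1] for i in range(1, n + 1) for j in range(1, n + 1))
    mu_y = sum(j * p[i - 1, j - 1] for i in range(1, n + 1) for j in range(1, n + 1))
    return sum(
        (i + j - mu_x - mu_y) ** 3 * p[i - 1, j - 1]
        for i in range(1, n + 1) for j in range(1, n + 1)
    )


def brute_zones(bins: np.ndarray, roi: np.ndarray) -> list[tuple[int, int]]:
    """(grey level, size) of every maximal connected equal-value zone.

    Flood fill with full neighbourhood connectivity (8 in 2D, 26 in 3D).
    """
    offsets = [
        off for off in itertools.product((-1, 0, 1), repeat=bins.ndim)
        if any(o != 0 for o in off)
    ]
    seen = np.zeros(bins.shape, dtype=bool)
    zones = []
    for start in itertools.product(*[range(s) for s in bins.shape]):
        if seen[start] or not roi[start]:
            continue
        level = bins[start]
        stack, size = [start], 0
        seen[start] = True
        while stack:
            cur = stack.pop()
            size += 1
            for off in offsets:
                nb = tuple(i + o for i, o in zip(cur, off))
                if any(j < 0 or j >= s for j, s in zip(nb, bins.shape)):
                    continue
                if seen[nb] or not roi[nb] or bins[nb] != level:
                    continue
                seen[nb] = True
                stack.append(nb)
        zones.append((int(level), size))
    return zones


def brute_zone_matrix(bins: np.ndarray, roi: np.ndarray, n_bins: int) -> np.ndarray:
    zones = brute_zones(bins, roi)
    max_size = max(s for _, s in zones)
    s = np.zeros((n_bins, max_size), dtype=np.int64)
    for level, size in zones:
        s[level - 1, size - 1] += 1
    return s


def brute_zone_size_entropy(s: np.ndarray) -> float:
    p = s / s.sum()
    return float(-sum(q * np.log2(q) for q in p.ravel() if q > 0))


def brute_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC by exhaustive positive-negative pair counting with half ties."""
    pos = [v for v, l in zip(values, labels) if l]
    neg = [v for v, l in zip(values, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
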