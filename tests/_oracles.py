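"""Independent brute-force oracles used by the tests.

These deliberately use naive pair enumeration and direct sums so they share
no code path with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_bruteforce(levels: np.ndarray, L: int, angle: int, d: int, symmetric=True):
    """Co-occurrence counts by explicit double loop over all pixels."""
    dr, dc = OFFSETS[angle]
    dr, dc = dr * d, dc * d
    nr, nc = levels.shape
    counts = np.zeros((L, L), dtype=np.int64)
    for r in range(nr):
        for c in range(nc):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc:
                counts[levels[r, c], levels[r2, c2]] += 1
                if symmetric:
                    counts[levels[r2, c2], levels[r, c]] += 1
    return counts


def haralick_bruteforce(counts: np.ndarray):
    """The four texture measures by direct summation over matrix cells."""
    n = counts.sum()
    L = counts.shape[0]
    p = counts / n
    contrast = 0.0
    energy = 0.0
    homogeneity = 0.0
    mu_i = mu_j = 0.0
    for i in range(L):
        for j in range(L):
            contrast += (i - j) ** 2 * p[i, j]
            energy += p[i, j] ** 2
            homogeneity += p[i, j] / (1 + abs(i - j))
            mu_i += i * p[i, j]
            mu_j += j * p[i, j]
    var_i = var_j = cov = 0.0
    for i in range(L):
        for j in range(L):
            var_i += (i - mu_i) ** 2 * p[i, j]
            var_j += (j - mu_j) ** 2 * p[i, j]
            cov += (i - mu_i) * (j - mu_j) * p[i, j]
    denom = math.sqrt(var_i * var_j)
    correlation = cov / denom if denom > 0 else float("nan")
    return contrast, correlation, energy, homogeneity


def grating(shape, angle_deg, period_px=8.0):
    """Sinusoidal grating whose stripes run along ``angle_deg`` from vertical."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    th = math.radians(angle_deg)
    # coordinate perpendicular to the stripe direction (cos th, sin th)
    perp = -rows * math.sin(th) + cols * math.cos(th)
    return np.sin(2 * np.pi * perp / period_px)
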