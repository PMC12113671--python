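"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle reimplements an operation from first principles (explicit
loops, exhaustive search, direct least squares) with no shared code path
with the library implementation it checks.
"""

from __future__ import annotations

import numpy as np


def otsu_between_class_variance(
    image: np.ndarray, threshold: float, nbins: int = 256
) -> float:
    """Between-class variance of the 256-bin split induced by *threshold*."""
    hist, edges = np.histogram(image.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    lo = centers <= threshold
    w0, w1 = hist[lo].sum(), hist[~lo].sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = (hist[lo] * centers[lo]).sum() / w0
    mu1 = (hist[~lo] * centers[~lo]).sum() / w1
    total = hist.sum()
    return float((w0 / total) * (w1 / total) * (mu0 - mu1) ** 2)


def otsu_brute_force(image: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive 256-bin between-class-variance threshold search."""
    hist, edges = np.histogram(image.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best_var, best_t = -1.0, centers[0]
    total = hist.sum()
    for t in range(1, nbins):
        w0, w1 = hist[:t].sum(), hist[t:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:t] * centers[:t]).sum() / w0
        mu1 = (hist[t:] * centers[t:]).sum() / w1
        var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[t - 1]
    return float(best_t)


def spa_chain_gram_schmidt(X: np.ndarray, start: int, max_len: int) -> list[int]:
    """SPA recursion with explicit Gram–Schmidt at every step.

    At each step, orthogonalize every unselected (mean-centered) column
    against the full selected set from scratch and pick the largest
    residual norm.
    """
    Xc = X - X.mean(axis=0, keepdims=True)
    B = Xc.shape[1]
    chain = [start]
    while len(chain) < max_len:
        # orthonormal basis of the selected columns
        basis: list[np.ndarray] = []
        for j in chain:
            v = Xc[:, j].copy()
            for b in basis:
                v -= (b @ v) * b
            nrm = np.linalg.norm(v)
            if nrm > 1e-12:
                basis.append(v / nrm)
        best_norm, best_j = -1.0, None
        for j in range(B):
            if j in chain:
                continue
            r = Xc[:, j].copy()
            for b in basis:
                r -= (b @ r) * b
            nrm = np.linalg.norm(r) ** 2
            if nrm > best_norm + 1e-12:
                best_norm, best_j = nrm, j
        if best_j is None or best_norm <= 1e-12:
            break
        chain.append(best_j)
    return chain


def sync_spectrum_loops(series: np.ndarray) -> np.ndarray:
    """Synchronous correlation spectrum by explicit double summation."""
    m, B = series.shape
    mean = series.mean(axis=0)
    phi = np.zeros((B, B))
    for v1 in range(B):
        for v2 in range(B):
            s = 0.0
            for j in range(m):
                s += (series[j, v1] - mean[v1]) * (series[j, v2] - mean[v2])
            phi[v1, v2] = s / (m - 1)
    return phi


def kennard_stone_naive(X: np.ndarray, n_select: int) -> list[int]:
    """Greedy max-min KS with an O(n^2) distance scan at every step."""
    n = X.shape[0]

    def dist(i: int, j: int) -> float:
        return float(np.linalg.norm(X[i] - X[j]))

    best_pair, best_d = (0, 1), -1.0
    for i in range(n):
        for j in range(i + 1, n):
            if dist(i, j) > best_d:
                best_d, best_pair = dist(i, j), (i, j)
    chosen = list(best_pair)
    while len(chosen) < n_select:
        best_i, best_min = None, -1.0
        for i in range(n):
            if i in chosen:
                continue
            mind = min(dist(i, j) for j in chosen)
            if mind > best_min:
                best_min, best_i = mind, i
        chosen.append(best_i)
    return sorted(chosen)


def sg_window_fits(row: np.ndarray) -> np.ndarray:
    """Interior Savitzky–Golay 5-3 values by direct per-window cubic fits."""
    B = row.size
    out = np.full(B, np.nan)
    x = np.arange(-2.0, 3.0)
    for i in range(2, B - 2):
        coeffs = np.polyfit(x, row[i - 2 : i + 3], deg=3)
        out[i] = np.polyval(coeffs, 0.0)
    return out
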