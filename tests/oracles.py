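"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — explicit loops, textbook formulas,
eigendecomposition of X X^T instead of an SVD — and shares no code with the
package routines it checks.
"""

from __future__ import annotations

import numpy as np


def hankel_entry(series: np.ndarray, i: int, j: int) -> float:
    """Trajectory-matrix entry by the index identity entry(i, j) = x[i + j]."""
    return float(series[i + j])


def ssa_via_gram(series, L):
    """SSA eigentriples from the eigendecomposition of S = X X^T.

    Returns (sigma, U, V) with sigma descending, columns of U/V unit norm.
    Signs follow the same convention as the package (largest-|entry| of
    each U column positive) so results are directly comparable.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    K = n - L + 1
    X = np.empty((L, K))
    for i in range(L):
        for j in range(K):
            X[i, j] = hankel_entry(x, i, j)
    S = X @ X.T
    lam, U = np.linalg.eigh(S)
    order = np.argsort(lam)[::-1]
    lam, U = lam[order], U[:, order]
    lam = np.clip(lam, 0.0, None)
    keep = lam > (lam[0] * 1e-20 if lam[0] > 0 else 0)
    lam, U = lam[keep], U[:, keep]
    sigma = np.sqrt(lam)
    V = np.empty((K, sigma.size))
    for i in range(sigma.size):
        V[:, i] = X.T @ U[:, i] / sigma[i]
    for i in range(sigma.size):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            V[:, i] = -V[:, i]
    return sigma, U, V


def antidiagonal_mean(matrix: np.ndarray) -> np.ndarray:
    """Series whose n-th sample is the mean over the anti-diagonal i+j = n."""
    L, K = matrix.shape
    n = L + K - 1
    out = np.zeros(n)
    for s in range(n):
        vals = [matrix[i, s - i]
                for i in range(L) if 0 <= s - i < K]
        out[s] = np.mean(vals)
    return out


def reconstruct_group(series, L, indices_1based):
    """Brute-force reconstruction of one eigentriple group."""
    sigma, U, V = ssa_via_gram(series, L)
    acc = np.zeros((U.shape[0], V.shape[0]))
    for i in indices_1based:
        k = i - 1
        acc += sigma[k] * np.outer(U[:, k], V[:, k])
    return antidiagonal_mean(acc)


def kruskal_h_by_hand(groups):
    """Kruskal-Wallis H from first principles: midranks + tie correction."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = pooled.size
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = np.mean(np.arange(i + 1, j + 1))
        i = j
    h = 0.0
    start = 0
    for g in groups:
        g = np.asarray(g)
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def lognormal_sum_median(mu1, s1, mu2, s2, grid_n=2**15, tmax=60.0):
    """Median of lognormal(mu1, s1) + lognormal(mu2, s2) by convolution."""
    from scipy.stats import lognorm

    dt = tmax / grid_n
    t = np.arange(grid_n) * dt + dt / 2
    p1 = lognorm.pdf(t, s1, scale=np.exp(mu1)) * dt
    p2 = lognorm.pdf(t, s2, scale=np.exp(mu2)) * dt
    psum = np.convolve(p1, p2)[:grid_n]
    cdf = np.cumsum(psum)
    cdf /= cdf[-1]
    idx = int(np.searchsorted(cdf, 0.5))
    return float((idx + 1) * dt)
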