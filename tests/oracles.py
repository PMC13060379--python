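"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the code paths under test: shortest paths by
Floyd-Warshall recursion written out by hand, clustering by exhaustive
triple enumeration, local efficiency by explicit neighbour-subgraph
search, and REML by grid search over the restricted likelihood.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(L: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths from a length matrix (inf = absent)."""
    D = L.copy().astype(float)
    n = D.shape[0]
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def lengths(W: np.ndarray) -> np.ndarray:
    L = np.full_like(W, np.inf, dtype=float)
    nz = W > 0
    L[nz] = 1.0 / W[nz]
    np.fill_diagonal(L, 0.0)
    return L


def global_efficiency_bf(W: np.ndarray) -> float:
    n = W.shape[0]
    if n < 2:
        return 0.0
    D = floyd_warshall(lengths(W))
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                total += 1.0 / D[i, j]
    return total / (n * (n - 1))


def mean_clustering_bf(W: np.ndarray) -> float:
    n = W.shape[0]
    if W.max() == 0:
        return 0.0
    Wn = W / W.max()
    C = np.zeros(n)
    for i in range(n):
        k = int((W[i] > 0).sum())
        if k < 2:
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    s += (Wn[i, j] * Wn[i, h] * Wn[j, h]) ** (1.0 / 3.0)
        C[i] = s / (k * (k - 1))
    return float(C.mean())


def local_efficiency_bf(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    if W.max() == 0:
        return out
    Wn = W / W.max()
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = Wn[np.ix_(nbrs, nbrs)]
        D = floyd_warshall(lengths(sub))
        s = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(D[a, b]) and D[a, b] > 0:
                    s += (Wn[i, nbrs[a]] * Wn[i, nbrs[b]] / D[a, b]) ** (1.0 / 3.0)
        out[i] = s / (k * (k - 1))
    return out


def reml_grid(betas: np.ndarray, v: np.ndarray,
              tau_max: float = 1.0, n_grid: int = 200001):
    """Maximize the restricted log-likelihood over a fine tau^2 grid.

    Returns (beta_meta, tau2) at the grid optimum.
    """
    betas = np.asarray(betas, float)
    v = np.asarray(v, float)
    grid = np.linspace(0.0, tau_max, n_grid)
    best_ll, best_tau = -np.inf, 0.0
    for tau2 in grid:
        w = 1.0 / (v + tau2)
        mu = (w * betas).sum() / w.sum()
        ll = -0.5 * (np.log(v + tau2).sum() + np.log(w.sum())
                     + (w * (betas - mu) ** 2).sum())
        if ll > best_ll:
            best_ll, best_tau = ll, tau2
    w = 1.0 / (v + best_tau)
    return (w * betas).sum() / w.sum(), best_tau


def bh_stepup(p: np.ndarray, q: float):
    """Hand-rolled Benjamini-Hochberg step-up rejections and q-values."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    # largest k with p_(k) <= q k / m
    reject_upto = 0
    for k in range(1, m + 1):
        if ranked[k - 1] <= q * k / m:
            reject_upto = k
    reject = np.zeros(m, bool)
    reject[order[:reject_upto]] = True
    # q-values: cumulative minimum of m p_(k) / k from the top
    qvals_sorted = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    qvals = np.empty(m)
    qvals[order] = np.minimum(qvals_sorted, 1.0)
    return qvals, reject
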