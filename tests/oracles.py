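"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in the most literal way possible
(dense matrices, explicit loops over the defining formulas) and shares no
code with the package's own computation paths.
"""

from __future__ import annotations

import math

import numpy as np


def mean_degree_naive(adj: np.ndarray) -> float:
    n = adj.shape[0]
    return sum(int(adj[i, j]) for i in range(n) for j in range(n)) / n


def floyd_warshall_efficiency(adj: np.ndarray) -> float:
    """Global efficiency from dense Floyd–Warshall all-pairs distances."""
    n = adj.shape[0]
    inf = math.inf
    d = [[0 if i == j else (1 if adj[i, j] else inf) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and d[i][j] < inf:
                total += 1.0 / d[i][j]
    return total / (n * (n - 1))


def modularity_naive(adj: np.ndarray, labels) -> float:
    """Double loop over the defining sum, including i == j terms."""
    n = adj.shape[0]
    deg = [sum(int(adj[i, j]) for j in range(n)) for i in range(n)]
    two_k = sum(deg)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] - deg[i] * deg[j] / two_k
    return q / two_k


def clustering_naive(adj: np.ndarray, exclude_low_degree: bool = False) -> float:
    """Per-node triangle proportion by exhaustive triple enumeration."""
    n = adj.shape[0]
    cs = []
    for i in range(n):
        neigh = [j for j in range(n) if adj[i, j]]
        d = len(neigh)
        if d < 2:
            if not exclude_low_degree:
                cs.append(0.0)
            continue
        closed = 0
        for j in neigh:
            for h in neigh:
                if j != h and adj[j, h]:
                    closed += 1
        cs.append(closed / (d * (d - 1)))
    return sum(cs) / len(cs) if cs else 0.0


def bh_stepup_naive(pvals, q: float) -> np.ndarray:
    """Benjamini–Hochberg step-up: boolean rejection mask, original order."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def pearson_naive(x, y) -> float:
    """Sample correlation from the raw-sums formula."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def random_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Dense symmetric 0/1 adjacency with empty diagonal."""
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T
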