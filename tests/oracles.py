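"""Independent brute-force oracles used to cross-check the library.

Everything here is deliberately naive (Floyd-Warshall, explicit triple
enumeration, path-count dynamic programming, residual regression) and avoids
the code paths — networkx, the vectorized partial-correlation sweep — that it
is used to verify.
"""
from __future__ import annotations

import numpy as np
from scipy import stats


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path distances (inf when unreachable)."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[adj > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def mean_path_brute(adj: np.ndarray, subset: list[int]) -> float:
    dist = floyd_warshall(adj)
    total, pairs = 0.0, 0
    for a in range(len(subset)):
        for b in range(a + 1, len(subset)):
            d = dist[subset[a], subset[b]]
            if not np.isfinite(d):
                raise ValueError("subset disconnected")
            total += d
            pairs += 1
    return total / pairs


def transitivity_brute(adj: np.ndarray) -> float:
    """3 * triangles / connected triples via explicit enumeration."""
    n = adj.shape[0]
    triangles = 0
    triples = 0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if i == j or j == k or i == k:
                    continue
                if adj[i, j] and adj[j, k]:
                    triples += 1  # ordered path i-j-k centered at j
                    if adj[i, k]:
                        triangles += 1
    # ordered counting: each triangle counted 6 times, each triple twice
    return 0.0 if triples == 0 else triangles / triples


def betweenness_brute(adj: np.ndarray) -> np.ndarray:
    """Endpoint-excluded betweenness with fractional credit for tied paths."""
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = np.argsort(dist[s])
        for t in order:
            if t == s or not np.isfinite(dist[s, t]):
                continue
            preds = [u for u in range(n) if adj[u, t] and dist[s, u] == dist[s, t] - 1]
            sigma[s, t] = sum(sigma[s, u] for u in preds)
    btw = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if v in (s, t) or not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    btw[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return btw


def rank_residual_partial(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Spearman first-order partial via residual regression on mid-ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rz = stats.rankdata(z)
    design = np.column_stack([np.ones_like(rz), rz])
    bx, *_ = np.linalg.lstsq(design, rx, rcond=None)
    by, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ bx
    ey = ry - design @ by
    return float(np.corrcoef(ex, ey)[0, 1])


def random_graph_adj(n: int, p_edge: float, rng: np.random.Generator) -> np.ndarray:
    adj = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                adj[i, j] = adj[j, i] = 1.0
    return adj
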