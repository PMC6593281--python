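"""Brute-force reference implementations used as independent oracles.

Deliberately naive: explicit loops, Floyd-Warshall distances, exhaustive
enumeration of shortest paths. They share no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bf_clustering(adj: np.ndarray) -> tuple[np.ndarray, float]:
    n = adj.shape[0]
    coefs = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b])
        coefs[i] = 2.0 * tri / (k * (k - 1))
    return coefs, float(coefs.mean())


def bf_distances(adj: np.ndarray) -> np.ndarray:
    """Floyd-Warshall."""
    n = adj.shape[0]
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0.0)
    d[adj > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def bf_char_path(adj: np.ndarray) -> float:
    d = bf_distances(adj)
    n = adj.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(i + 1, n) if math.isfinite(d[i, j])]
    return float(np.mean(vals))


def bf_global_efficiency(adj: np.ndarray) -> float:
    d = bf_distances(adj)
    n = adj.shape[0]
    total = sum(1.0 / d[i, j] for i in range(n) for j in range(n) if i != j and math.isfinite(d[i, j]))
    return total / (n * (n - 1))


def bf_nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    d = bf_distances(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(1.0 / d[i, j] for j in range(n) if j != i and math.isfinite(d[i, j])) / (n - 1)
    return out


def bf_local_efficiency(adj: np.ndarray) -> tuple[np.ndarray, float]:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        out[i] = bf_global_efficiency(sub)
    return out, float(out.mean())


def _all_shortest_paths(adj: np.ndarray, s: int, t: int, d: np.ndarray) -> list[tuple[int, ...]]:
    """Every shortest s-t path, by DFS bounded by the distance matrix."""
    if not math.isfinite(d[s, t]):
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for v in range(adj.shape[0]):
            if adj[u, v] and d[s, v] == len(path) and d[v, t] == d[s, t] - len(path):
                extend(path + [v])

    extend([s])
    return paths


def bf_betweenness(adj: np.ndarray) -> np.ndarray:
    """Endpoint-excluded betweenness, each unordered pair counted once."""
    n = adj.shape[0]
    d = bf_distances(adj)
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, s, t, d)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    out[v] += 1.0 / len(paths)
    return out
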