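"""Compiled inner loops for null-ensemble generation.

Normalizing gamma/lambda/sigma needs ~100 degree-preserving rewired graphs per
subject per sparsity value — hundreds of thousands of rewire+measure cycles per
cohort — so the double-edge-swap loop, triangle counting and all-pairs BFS are
fused into one numba kernel. A pure-NumPy fallback with identical semantics
(but a different random stream) is used when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

# Attempt budget: a proposed swap is rejected (and retried) when it would create
# a self-loop or multi-edge; give up after this many attempts per target swap.
ATTEMPT_FACTOR = 20


@njit(cache=True)
def _swap_edges(adj, edges, n_target, max_attempts):
    """Maslov-Sneppen double-edge swaps in place; returns successful swap count."""
    m = edges.shape[0]
    successes = 0
    attempts = 0
    while successes < n_target and attempts < max_attempts:
        attempts += 1
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        u, v = edges[e1, 0], edges[e1, 1]
        x, y = edges[e2, 0], edges[e2, 1]
        if np.random.randint(0, 2) == 1:
            x, y = y, x
        # proposed new edges: (u, y) and (x, v)
        if u == y or x == v or u == x or v == y:
            continue
        if adj[u, y] == 1 or adj[x, v] == 1:
            continue
        adj[u, v] = 0
        adj[v, u] = 0
        adj[x, y] = 0
        adj[y, x] = 0
        adj[u, y] = 1
        adj[y, u] = 1
        adj[x, v] = 1
        adj[v, x] = 1
        edges[e1, 0], edges[e1, 1] = u, y
        edges[e2, 0], edges[e2, 1] = x, v
        successes += 1
    return successes


@njit(cache=True)
def _build_csr(edges, n):
    """Neighbor lists in CSR form (indptr, indices) from an (m, 2) edge list."""
    m = edges.shape[0]
    deg = np.zeros(n, dtype=np.int64)
    for e in range(m):
        deg[edges[e, 0]] += 1
        deg[edges[e, 1]] += 1
    indptr = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        indptr[i + 1] = indptr[i] + deg[i]
    fill = indptr[:-1].copy()
    indices = np.empty(2 * m, dtype=np.int64)
    for e in range(m):
        u, v = edges[e, 0], edges[e, 1]
        indices[fill[u]] = v
        fill[u] += 1
        indices[fill[v]] = u
        fill[v] += 1
    return indptr, indices


@njit(cache=True)
def _mean_clustering(adj, indptr, indices):
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        lo, hi = indptr[i], indptr[i + 1]
        k = hi - lo
        if k < 2:
            continue
        tri = 0
        for a in range(lo, hi):
            na = indices[a]
            for b in range(a + 1, hi):
                if adj[na, indices[b]] == 1:
                    tri += 1
        total += 2.0 * tri / (k * (k - 1))
    return total / n


@njit(cache=True)
def _lp_finite(indptr, indices, n):
    """Mean BFS distance over finite unordered pairs; (-1, n_pairs) if none exist."""
    dist = np.empty(n, dtype=np.int64)
    queue = np.empty(n, dtype=np.int64)
    total = 0.0
    n_finite = 0
    n_pairs = n * (n - 1) // 2
    for s in range(n):
        for i in range(n):
            dist[i] = -1
        dist[s] = 0
        queue[0] = s
        head = 0
        tail = 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for a in range(indptr[u], indptr[u + 1]):
                w = indices[a]
                if dist[w] < 0:
                    dist[w] = du + 1
                    queue[tail] = w
                    tail += 1
        for t in range(s + 1, n):
            if dist[t] > 0:
                total += dist[t]
                n_finite += 1
    if n_finite == 0:
        return -1.0, n_pairs
    return total / n_finite, n_pairs - n_finite


@njit(cache=True)
def _null_ensemble_cp_lp(adj, edges, n_nulls, swaps_per_edge, seed):
    """cp and lp (finite-pair policy) for ``n_nulls`` degree-preserving rewirings."""
    np.random.seed(seed)
    m = edges.shape[0]
    n_target = m * swaps_per_edge
    max_attempts = n_target * ATTEMPT_FACTOR
    n = adj.shape[0]
    cps = np.empty(n_nulls)
    lps = np.empty(n_nulls)
    for r in range(n_nulls):
        a = adj.copy()
        e = edges.copy()
        _swap_edges(a, e, n_target, max_attempts)
        indptr, indices = _build_csr(e, n)
        cps[r] = _mean_clustering(a, indptr, indices)
        lp, _ = _lp_finite(indptr, indices, n)
        lps[r] = lp
    return cps, lps


def _swap_edges_py(adj, edges, n_target, max_attempts, rng):
    """Pure-python twin of ``_swap_edges`` (its own random stream)."""
    m = edges.shape[0]
    successes = 0
    attempts = 0
    while successes < n_target and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if rng.integers(0, 2) == 1:
            x, y = y, x
        if u == y or x == v or u == x or v == y:
            continue
        if adj[u, y] or adj[x, v]:
            continue
        adj[u, v] = adj[v, u] = 0
        adj[x, y] = adj[y, x] = 0
        adj[u, y] = adj[y, u] = 1
        adj[x, v] = adj[v, x] = 1
        edges[e1] = u, y
        edges[e2] = x, v
        successes += 1
    return successes
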