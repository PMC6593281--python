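"""Global and nodal topological metrics on binary undirected graphs.

Global: mean clustering coefficient Cp, characteristic path length Lp, global
efficiency E_glob, local efficiency E_loc. Nodal: degree, nodal efficiency,
betweenness. All are computed on the dense adjacency matrix; shortest paths
come from breadth-first search (unweighted graphs), betweenness from Brandes'
algorithm with endpoints excluded.

Disconnected graphs can occur at low sparsity. Lp has no finite value for
unreachable pairs, so the default policy averages finite-distance pairs only
and reports the count of infinite pairs; a ``"lcc"`` policy restricting to the
largest connected component is available. Efficiencies need no policy because
1/inf = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "nodal_degree",
    "clustering",
    "shortest_path_lengths",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "nodal_efficiency",
    "betweenness",
    "global_metrics",
    "nodal_metrics",
]


@dataclass(frozen=True)
class GlobalMetrics:
    """Raw (unnormalized) global metrics of one graph."""

    cp: float
    lp: float
    e_glob: float
    e_loc: float
    n_infinite_pairs: int = 0


@dataclass(frozen=True)
class NodalMetrics:
    """Per-node metric vectors of one graph."""

    degree: np.ndarray
    efficiency: np.ndarray
    betweenness: np.ndarray


def _adj(g) -> np.ndarray:
    a = getattr(g, "adjacency", g)
    return np.asarray(a)


def nodal_degree(g) -> np.ndarray:
    """Degree of every node (row sums of the adjacency matrix)."""
    return _adj(g).sum(axis=1).astype(np.int64)


def clustering(g) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean Cp.

    For node i with degree k_i >= 2 the coefficient is
    ``2 t_i / (k_i (k_i - 1))`` with t_i the number of triangles through i;
    nodes with degree < 2 contribute 0.
    """
    a = _adj(g).astype(np.float64)
    deg = a.sum(axis=1)
    tri = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = deg * (deg - 1)
    coef = np.zeros_like(deg)
    mask = denom > 0
    coef[mask] = 2.0 * tri[mask] / denom[mask]
    return coef, float(coef.mean())


def shortest_path_lengths(g) -> np.ndarray:
    """All-pairs BFS distance matrix; unreachable pairs are ``inf``."""
    a = _adj(g)
    return shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def characteristic_path_length(
    g, policy: str = "finite", dist: np.ndarray | None = None
) -> tuple[float, int]:
    """Mean shortest-path length Lp and the number of unreachable node pairs.

    ``policy="finite"`` averages over all finite-distance unordered pairs;
    ``policy="lcc"`` averages within the largest connected component.
    Raises if no pair has a finite distance (edgeless graph).
    """
    a = _adj(g)
    n = a.shape[0]
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    d = shortest_path_lengths(g) if dist is None else dist
    iu, ju = np.triu_indices(n, k=1)
    dv = d[iu, ju]
    n_inf = int(np.isinf(dv).sum())
    if policy == "finite":
        finite = dv[np.isfinite(dv)]
        if finite.size == 0:
            raise ValueError("graph has no connected pairs; Lp undefined")
        return float(finite.mean()), n_inf
    if policy == "lcc":
        _, labels = connected_components(csr_matrix(a), directed=False)
        sizes = np.bincount(labels)
        comp = np.flatnonzero(labels == sizes.argmax())
        if comp.size < 2:
            raise ValueError("largest component has fewer than 2 nodes; Lp undefined")
        sub = d[np.ix_(comp, comp)]
        si, sj = np.triu_indices(comp.size, k=1)
        return float(sub[si, sj].mean()), n_inf
    raise ValueError(f"unknown disconnection policy {policy!r}")


def global_efficiency(g, dist: np.ndarray | None = None) -> float:
    """Mean inverse shortest-path length over node pairs (1/inf = 0)."""
    a = _adj(g)
    n = a.shape[0]
    if n < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    d = shortest_path_lengths(g) if dist is None else dist
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(d)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(g, dist: np.ndarray | None = None) -> np.ndarray:
    """Per-node mean inverse distance to every other node."""
    a = _adj(g)
    n = a.shape[0]
    if n < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    d = shortest_path_lengths(g) if dist is None else dist
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(d)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def local_efficiency(g) -> tuple[np.ndarray, float]:
    """Per-node local efficiency and its mean E_loc.

    The local efficiency of node i is the global efficiency of the subgraph
    induced on i's neighbors (0 when degree < 2).
    """
    a = _adj(g)
    n = a.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        vals[i] = global_efficiency(a[np.ix_(nbrs, nbrs)])
    return vals, float(vals.mean())


def betweenness(g, normalized: bool = False) -> np.ndarray:
    """Brandes betweenness centrality, endpoints excluded.

    Unnormalized by default: node i's value is the sum over pairs (s, t),
    s != i != t, of the fraction of shortest s-t paths through i, each
    unordered pair counted once.
    """
    a = _adj(g)
    graph = nx.from_numpy_array(a)
    bc = nx.betweenness_centrality(graph, normalized=normalized)
    return np.array([bc[i] for i in range(a.shape[0])], dtype=float)


def global_metrics(g, policy: str = "finite") -> GlobalMetrics:
    """All four raw global metrics, sharing one distance computation."""
    d = shortest_path_lengths(g)
    _, cp = clustering(g)
    lp, n_inf = characteristic_path_length(g, policy=policy, dist=d)
    e_glob = global_efficiency(g, dist=d)
    _, e_loc = local_efficiency(g)
    return GlobalMetrics(cp=cp, lp=lp, e_glob=e_glob, e_loc=e_loc, n_infinite_pairs=n_inf)


def nodal_metrics(g) -> NodalMetrics:
    """All three nodal metric vectors."""
    d = shortest_path_lengths(g)
    return NodalMetrics(
        degree=nodal_degree(g),
        efficiency=nodal_efficiency(g, dist=d),
        betweenness=betweenness(g),
    )
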