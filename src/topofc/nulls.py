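"""Degree-preserving null networks and the normalized small-world metrics.

Raw clustering and path length scale with density, so they are normalized by
the means of an ensemble of random networks with exactly the same degree
sequence (Maslov-Sneppen double-edge swaps):

    gamma = Cp / <Cp_null>,   lambda = Lp / <Lp_null>,   sigma = gamma / lambda.

A network is called small-world when gamma > 1 with lambda ~ 1, i.e. sigma > 1.
The ensemble size defaults to 100 nulls per graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .connectivity import BinaryGraph
from .metrics import characteristic_path_length, clustering

__all__ = ["NullEnsembleConfig", "NormalizedGlobalMetrics", "rewire_preserving_degree", "normalized_metrics"]


@dataclass(frozen=True)
class NullEnsembleConfig:
    """Settings for the null ensemble: 100 rewired networks, 10 swaps per edge."""

    n_nulls: int = 100
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nulls < 1:
            raise ValueError("n_nulls must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")


@dataclass(frozen=True)
class NormalizedGlobalMetrics:
    """gamma, lambda, sigma plus the null-ensemble statistics behind them."""

    gamma: float
    lam: float
    sigma: float
    cp_null_mean: float
    cp_null_sd: float
    lp_null_mean: float
    lp_null_sd: float
    n_nulls: int


def rewire_preserving_degree(g: BinaryGraph, swaps_per_edge: int = 10, seed: int = 0) -> BinaryGraph:
    """One degree-preserving randomization of ``g`` by double-edge swaps.

    Two random edges (u,v), (x,y) are replaced by (u,y), (x,v) whenever that
    creates no self-loop or duplicate edge; each node keeps its exact degree.
    Targets ``swaps_per_edge * m`` successful swaps with an attempt budget of
    ``ATTEMPT_FACTOR`` times that; saturated graphs (no legal swap, e.g.
    complete graphs) are returned unchanged with a warning.
    """
    m = g.edge_count
    if m < 2:
        raise ValueError("rewiring needs at least 2 edges")
    adj = g.adjacency.astype(np.uint8).copy()
    edges = g.edges()
    n_target = m * swaps_per_edge
    rng = np.random.default_rng(seed)
    successes = _kernels._swap_edges_py(adj, edges, n_target, n_target * _kernels.ATTEMPT_FACTOR, rng)
    if successes == 0:
        warnings.warn("no legal double-edge swap found; graph returned unchanged (saturated?)", stacklevel=2)
    return BinaryGraph(adjacency=adj, sparsity=g.sparsity)


def null_cp_lp_ensemble(g: BinaryGraph, cfg: NullEnsembleConfig) -> tuple[np.ndarray, np.ndarray]:
    """cp and lp for each of ``cfg.n_nulls`` independent rewirings of ``g``.

    Uses the compiled kernel when numba is importable; otherwise falls back to
    the pure-python path (same null model, different random stream).
    """
    m = g.edge_count
    if m < 2:
        raise ValueError("null ensemble needs at least 2 edges")
    adj = g.adjacency.astype(np.uint8)
    edges = g.edges()
    seed = int(cfg.seed) % (2**31 - 1)
    if _kernels.NUMBA_AVAILABLE:
        cps, lps = _kernels._null_ensemble_cp_lp(adj, edges, cfg.n_nulls, cfg.swaps_per_edge, seed)
    else:  # pragma: no cover - exercised only without numba
        rng = np.random.default_rng(seed)
        cps = np.empty(cfg.n_nulls)
        lps = np.empty(cfg.n_nulls)
        n_target = m * cfg.swaps_per_edge
        for r in range(cfg.n_nulls):
            a = adj.copy()
            e = edges.copy()
            _kernels._swap_edges_py(a, e, n_target, n_target * _kernels.ATTEMPT_FACTOR, rng)
            _, cps[r] = clustering(a)
            lps[r], _ = characteristic_path_length(a)
    if np.any(lps < 0):
        raise ValueError("a null network had no connected pairs; Lp undefined")
    return cps, lps


def normalized_metrics(g: BinaryGraph, cfg: NullEnsembleConfig) -> NormalizedGlobalMetrics:
    """gamma, lambda and sigma of ``g`` against its degree-preserving null ensemble."""
    _, cp = clustering(g.adjacency)
    lp, _ = characteristic_path_length(g.adjacency)
    cps, lps = null_cp_lp_ensemble(g, cfg)
    cp_mean = float(cps.mean())
    lp_mean = float(lps.mean())
    if cp_mean == 0:
        raise ValueError("null ensemble mean clustering is zero (triangle-free nulls); gamma undefined")
    if lp_mean == 0:
        raise ValueError("null ensemble mean path length is zero; lambda undefined")
    gamma = cp / cp_mean
    lam = lp / lp_mean
    return NormalizedGlobalMetrics(
        gamma=gamma,
        lam=lam,
        sigma=gamma / lam,
        cp_null_mean=cp_mean,
        cp_null_sd=float(cps.std(ddof=1)) if len(cps) > 1 else 0.0,
        lp_null_mean=lp_mean,
        lp_null_sd=float(lps.std(ddof=1)) if len(lps) > 1 else 0.0,
        n_nulls=cfg.n_nulls,
    )
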