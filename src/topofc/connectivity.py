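"""Functional connectivity: Pearson FC matrices and sparsity-thresholded binary graphs.

Edges are Pearson correlations between region time series. Weighted matrices are
binarized at fixed *sparsity* — every subject's network keeps exactly the same
number of edges, ``round(sp * N(N-1)/2)`` — so group differences reflect
topology, not overall connectivity strength. The r-to-z (``atanh``) map is
monotone, so ranking edges by r or by z yields identical binary graphs; the z
matrix is retained for reporting only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import SparsityGrid, SubjectTimeSeries

__all__ = [
    "FCMatrix",
    "BinaryGraph",
    "pearson_matrix",
    "fisher_z",
    "sparsity_binarize",
    "build_graph_series",
    "target_edge_count",
    "fc_to_csv",
    "fc_from_csv",
    "graph_to_edge_list",
]

_Z_CLIP = 1.0 - 1e-7  # |r| clipped here before atanh when building whole-matrix z maps


@dataclass
class FCMatrix:
    """Symmetric Pearson correlation matrix with region labels.

    The diagonal is set to zero by convention (self-correlations carry no
    network information). ``z`` is the Fisher r-to-z transform of the
    off-diagonal entries, with |r| clipped at ``1 - 1e-7`` so that perfectly
    correlated pairs map to a large finite value.
    """

    r: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric")
        off = r[~np.eye(r.shape[0], dtype=bool)]
        if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        r = (r + r.T) / 2.0
        np.fill_diagonal(r, 0.0)
        self.r = r
        if not self.labels:
            self.labels = [f"R{i + 1}" for i in range(r.shape[0])]
        if len(self.labels) != r.shape[0]:
            raise ValueError("label count does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]

    @property
    def z(self) -> np.ndarray:
        z = np.arctanh(np.clip(self.r, -_Z_CLIP, _Z_CLIP))
        np.fill_diagonal(z, 0.0)
        return z


@dataclass
class BinaryGraph:
    """Undirected, unweighted network at one sparsity value."""

    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if not np.all((adj == 0) | (adj == 1)):
            raise ValueError("adjacency must be binary")
        self.adjacency = adj.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> np.ndarray:
        """(m, 2) array of edges (i < j), lexicographically ordered."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        keep = self.adjacency[iu, ju] == 1
        return np.column_stack([iu[keep], ju[keep]]).astype(np.int64)


def pearson_matrix(ts: SubjectTimeSeries) -> FCMatrix:
    """Sample Pearson correlation between every pair of region time series.

    Raises
    ------
    ValueError
        If the series has fewer than 3 time points or any region has zero
        variance (the offending region is named).
    """
    x = ts.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 time points for a correlation matrix")
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd <= 1e-12 * (np.abs(x).mean(axis=0) + 1.0))
    if bad.size:
        raise ValueError(f"zero-variance region(s) at column index {bad.tolist()} in subject {ts.subject_id!r}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    return FCMatrix(r=r)


def fisher_z(r, clip: bool = False):
    """Fisher r-to-z transform, ``z = atanh(r)``.

    With ``clip=False`` (default) values with |r| >= 1 raise; with
    ``clip=True`` they are clipped to ``1 - 1e-7`` first.
    """
    r = np.asarray(r, dtype=float)
    if clip:
        r = np.clip(r, -_Z_CLIP, _Z_CLIP)
    elif np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1 (pass clip=True to clip)")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def target_edge_count(n_nodes: int, sparsity: float) -> int:
    """Edge budget at a sparsity value: ``round(sp * N(N-1)/2)``, round-half-even."""
    return int(np.rint(sparsity * n_nodes * (n_nodes - 1) / 2.0))


def _ranked_edges(fc: FCMatrix, ranking: str) -> tuple[np.ndarray, np.ndarray]:
    """All candidate edges (i<j) sorted strongest-first under the ranking.

    ``ranking='signed'`` (default convention) ranks by descending signed r so
    strong negative correlations are never selected; ``ranking='absolute'``
    ranks by |r|. Ties break lexicographically on (i, j) for determinism.
    """
    n = fc.n_regions
    iu, ju = np.triu_indices(n, k=1)
    vals = fc.r[iu, ju]
    if ranking == "signed":
        key = -vals
    elif ranking == "absolute":
        key = -np.abs(vals)
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    order = np.lexsort((ju, iu, key))
    return iu[order], ju[order]


def sparsity_binarize(fc: FCMatrix, sp: float, ranking: str = "signed") -> BinaryGraph:
    """Binarize an FC matrix keeping exactly the ``round(sp*N(N-1)/2)`` strongest edges."""
    if not 0 < sp < 1:
        raise ValueError("sparsity must lie in (0, 1)")
    n = fc.n_regions
    m = target_edge_count(n, sp)
    if m < 1:
        raise ValueError(f"sparsity {sp} yields no edges for {n} nodes")
    ii, jj = _ranked_edges(fc, ranking)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[ii[:m], jj[:m]] = 1
    adj |= adj.T
    return BinaryGraph(adjacency=adj, sparsity=sp)


def fc_to_csv(fc: FCMatrix, path) -> None:
    """Write an FC matrix as a square CSV with region-label header and index."""
    import pandas as pd

    pd.DataFrame(fc.r, index=fc.labels, columns=fc.labels).to_csv(path)


def fc_from_csv(path) -> FCMatrix:
    """Read a square, labeled CSV back into an :class:`FCMatrix`."""
    import pandas as pd

    frame = pd.read_csv(path, index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError("FC CSV must be square with matching row/column labels")
    return FCMatrix(r=frame.to_numpy(dtype=float), labels=[str(c) for c in frame.columns])


def graph_to_edge_list(g: BinaryGraph, labels: list[str] | None = None):
    """Export a binary graph as a two-column edge-list DataFrame of region labels."""
    import pandas as pd

    edges = g.edges()
    if labels is None:
        labels = [f"R{i + 1}" for i in range(g.n_nodes)]
    if len(labels) != g.n_nodes:
        raise ValueError("label count does not match graph size")
    return pd.DataFrame(
        {"region_a": [labels[i] for i in edges[:, 0]], "region_b": [labels[j] for j in edges[:, 1]]}
    )


def build_graph_series(fc: FCMatrix, grid: SparsityGrid, ranking: str = "signed") -> list[BinaryGraph]:
    """One binary graph per grid value, sharing a single stable edge ranking.

    Because every graph keeps a prefix of the same ranked edge list, the edge
    set at a smaller sparsity is a subset of the edge set at any larger one.
    """
    n = fc.n_regions
    ii, jj = _ranked_edges(fc, ranking)
    graphs = []
    for sp in grid:
        m = target_edge_count(n, sp)
        if m < 1:
            raise ValueError(f"sparsity {sp} yields no edges for {n} nodes")
        adj = np.zeros((n, n), dtype=np.uint8)
        adj[ii[:m], jj[:m]] = 1
        adj |= adj.T
        graphs.append(BinaryGraph(adjacency=adj, sparsity=float(sp)))
    return graphs
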