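"""Synthetic two-group cohorts of BOLD-like ROI time series.

Each subject gets a latent Watts-Strogatz small-world graph; "patient" subjects
additionally receive triangle-closing edges (raising clustering and local
efficiency — the direction of the group effect the pipeline must detect). The
latent graph is mapped to a positive-definite correlation matrix via
``(I - cA)^{-1}`` rescaled to unit diagonal, from which band-limited Gaussian
series are drawn. Cognitive-score columns are generated with one score linked
linearly to a latent nodal metric, so partial-correlation recovery is testable
end to end. All randomness descends from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .atlas import region_labels
from .core import SubjectTimeSeries
from .prep import bandpass

__all__ = [
    "GroundTruthSpec",
    "CohortManifest",
    "make_small_world_graph",
    "perturb_group_graph",
    "adjacency_to_covariance",
    "simulate_timeseries",
    "generate_cohort",
]


@dataclass(frozen=True)
class GroundTruthSpec:
    """Ground-truth settings for a synthetic cohort.

    ``coupling_fraction`` places the interaction strength c at that fraction of
    the spectral bound 1/lambda_max of the (unperturbed) latent adjacency, so
    per-edge coupling is identical across groups and every covariance is safely
    positive definite. ``noise_sd`` adds white observation noise (thermal/scanner
    noise) on top of the unit-variance network signal.

    ``effect_kind`` selects how the patient group differs:

    - ``"lattice_shift"`` (default): patients are drawn with rewiring
      probability ``rewire_prob * (1 - effect_size)``, i.e. a larger fraction
      of within-neighborhood lattice edges is retained — raising clustering and
      local efficiency at a homogeneous degree sequence.
    - ``"triangle_edges"``: patients receive ``perturb_group_graph``'s
      triangle-closing edge additions (raises raw clustering, but also degree
      heterogeneity, which dilutes the *normalized* clustering).

    ``linked_region``/``linked_score`` define which cognitive score is generated
    from which latent nodal degree (slope/noise in score units per degree unit);
    ``score_group_delta`` shifts the patient group's linked score.
    """

    n_regions: int = 116
    lattice_degree: int = 8
    rewire_prob: float = 0.15
    coupling_fraction: float = 0.6
    effect_size: float = 0.8
    effect_kind: str = "lattice_shift"
    noise_sd: float = 1.0
    band: tuple[float, float] | None = (0.01, 0.08)
    tr_seconds: float = 2.0
    linked_region: int = 0
    linked_score: str = "score_moca"
    score_intercept: float = 26.0
    score_slope: float = 0.8
    score_noise_sd: float = 1.0
    score_group_delta: float = -1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 4:
            raise ValueError("n_regions must be >= 4")
        if self.lattice_degree % 2 != 0 or self.lattice_degree >= self.n_regions:
            raise ValueError("lattice_degree must be even and < n_regions")
        if not 0 <= self.rewire_prob <= 1:
            raise ValueError("rewire_prob must lie in [0, 1]")
        if not 0 < self.coupling_fraction < 1:
            raise ValueError("coupling_fraction must lie in (0, 1)")
        if not 0 <= self.effect_size <= 1:
            raise ValueError("effect_size must lie in [0, 1]")
        if self.effect_kind not in ("lattice_shift", "triangle_edges"):
            raise ValueError("effect_kind must be 'lattice_shift' or 'triangle_edges'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.linked_region < self.n_regions:
            raise ValueError("linked_region out of range")


def make_small_world_graph(n: int, k: int, p: float, seed: int = 0) -> np.ndarray:
    """Watts-Strogatz ring-lattice-with-rewiring adjacency matrix.

    Start from a ring lattice where every node connects to its ``k`` nearest
    neighbors, then rewire each edge with probability ``p``. Edge count is
    ``n*k/2`` for every ``p``; the graph stays simple.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if k % 2 != 0:
        raise ValueError("k must be even")
    if k >= n:
        raise ValueError("k must be < n")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    g = nx.watts_strogatz_graph(n, k, p, seed=int(seed))
    return nx.to_numpy_array(g, nodelist=range(n), dtype=np.uint8)


def perturb_group_graph(adj: np.ndarray, effect_size: float, seed: int = 0) -> np.ndarray:
    """Add triangle-closing edges: ``round(effect_size * m)`` new edges among
    non-adjacent node pairs that share at least one neighbor.

    Raises if ``effect_size > 0`` but no closable pair exists (e.g. complete
    graph). ``effect_size = 0`` returns the input unchanged.
    """
    if not 0 <= effect_size <= 1:
        raise ValueError("effect_size must lie in [0, 1]")
    adj = np.asarray(adj, dtype=np.uint8)
    if effect_size == 0:
        return adj.copy()
    n = adj.shape[0]
    a = adj.astype(np.int64)
    common = a @ a  # common-neighbor counts
    iu, ju = np.triu_indices(n, k=1)
    closable = (a[iu, ju] == 0) & (common[iu, ju] > 0)
    cand = np.flatnonzero(closable)
    if cand.size == 0:
        raise ValueError("no closable triangles: every 2-path is already closed")
    m = int(a.sum()) // 2
    n_add = min(int(np.rint(effect_size * m)), cand.size)
    rng = np.random.default_rng(seed)
    # Greedy: close the pair with the most common neighbors first (max triangle
    # gain per edge), updating common-neighbor counts incrementally.
    out = adj.copy()
    common = common.astype(np.int64)
    np.fill_diagonal(common, 0)
    closable_m = np.triu((out == 0), k=1) & (common > 0)
    for _ in range(n_add):
        gains = np.where(closable_m, common, -1)
        mx = gains.max()
        if mx < 1:
            break
        ties = np.argwhere(gains == mx)
        i, j = (int(v) for v in ties[rng.integers(len(ties))])
        out[i, j] = out[j, i] = 1
        closable_m[i, j] = False
        # new edge (i, j): every neighbor of i gains a common neighbor with j, and v.v.
        for x in np.flatnonzero(out[i]):
            if x != j:
                common[x, j] += 1
                common[j, x] += 1
                lo, hi = min(x, j), max(x, j)
                if out[lo, hi] == 0:
                    closable_m[lo, hi] = True
        for x in np.flatnonzero(out[j]):
            if x != i:
                common[x, i] += 1
                common[i, x] += 1
                lo, hi = min(x, i), max(x, i)
                if out[lo, hi] == 0:
                    closable_m[lo, hi] = True
    return out


def adjacency_to_covariance(adj: np.ndarray, coupling: float) -> np.ndarray:
    """Map a binary adjacency to a positive-definite correlation matrix.

    ``C = (I - c A)^{-1}`` rescaled to unit diagonal. Valid for
    ``0 <= c < 1/lambda_max(A)``; within that range all eigenvalues of
    ``I - cA`` are positive, so C is strictly positive definite, and entries
    decay with graph distance (adjacent pairs correlate most strongly).
    """
    a = np.asarray(adj, dtype=float)
    if coupling < 0:
        raise ValueError("coupling must be non-negative")
    if coupling > 0:
        lam_max = np.max(np.abs(np.linalg.eigvalsh(a)))
        if coupling * lam_max >= 1:
            raise ValueError(
                f"coupling {coupling} violates the spectral bound 1/lambda_max = {1 / lam_max:.6g}"
            )
    n = a.shape[0]
    cov = np.linalg.inv(np.eye(n) - coupling * a)
    cov = (cov + cov.T) / 2.0
    d = np.sqrt(np.diag(cov))
    cov = cov / np.outer(d, d)
    return (cov + cov.T) / 2.0


def simulate_timeseries(
    cov: np.ndarray,
    T: int,
    tr: float = 2.0,
    seed: int = 0,
    band: tuple[float, float] | None = (0.01, 0.08),
    subject_id: str = "",
) -> SubjectTimeSeries:
    """Zero-mean Gaussian series with covariance ``cov``, optionally band-limited.

    Band-limiting applies the same zero-phase filter to every column, which
    leaves the between-column correlation structure unchanged in expectation
    while giving the series a BOLD-like spectrum; columns are rescaled to unit
    variance afterwards. Only second-order structure matters downstream, so no
    hemodynamic model is attempted.
    """
    if T < 50:
        raise ValueError("T must be >= 50")
    cov = np.asarray(cov, dtype=float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive definite") from exc
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((T, cov.shape[0])) @ chol.T
    ts = SubjectTimeSeries(values=x, tr_seconds=tr, subject_id=subject_id)
    if band is not None:
        ts = bandpass(ts, low=band[0], high=band[1])
        sd = ts.values.std(axis=0)
        sd[sd == 0] = 1.0
        ts = ts.with_values(ts.values / sd)
    return ts


@dataclass
class CohortManifest:
    """Cohort table (one row per subject) plus generation metadata."""

    table: pd.DataFrame
    root: Path
    meta: dict = field(default_factory=dict)

    REQUIRED = ("subject_id", "group", "sex", "age_years", "education_years", "bmi", "series_path")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        self.root = Path(self.root)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def series(self, subject_id: str) -> SubjectTimeSeries:
        """Load one subject's time-series TSV."""
        row = self.table.loc[self.table["subject_id"] == subject_id]
        if row.empty:
            raise KeyError(f"unknown subject {subject_id!r}")
        path = self.root / row["series_path"].iloc[0]
        values = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
        tr = float(self.meta.get("tr_seconds", 2.0))
        return SubjectTimeSeries(values=values, tr_seconds=tr, subject_id=subject_id)

    @classmethod
    def load(cls, root: str | Path) -> "CohortManifest":
        root = Path(root)
        table = pd.read_csv(root / "manifest.csv")
        meta_path = root / "meta.yaml"
        meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
        return cls(table=table, root=root, meta=meta)


def _covariates(rng: np.random.Generator) -> dict:
    """Demographics resembling a middle-aged clinical cohort (matched across groups)."""
    return {
        "sex": "M" if rng.random() < 0.6 else "F",
        "age_years": float(np.clip(rng.normal(50.0, 6.5), 40, 65)),
        "education_years": float(np.clip(rng.normal(10.5, 3.4), 3, 20)),
        "bmi": float(np.clip(rng.normal(24.5, 3.0), 16, 38)),
    }


def generate_cohort(
    spec: GroundTruthSpec,
    n_per_group: int = 30,
    T: int = 185,
    seed: int | None = None,
    out_dir: str | Path = "cohort",
    force: bool = False,
) -> CohortManifest:
    """Generate a two-group cohort and write it to ``out_dir``.

    Writes one TSV per subject (T rows x N regions, header = region labels)
    plus ``manifest.csv`` and ``meta.yaml``. Per-subject latent graphs share
    the spec's Watts-Strogatz parameters; patients additionally receive the
    triangle-closing perturbation. The linked cognitive score is
    ``intercept + slope * (latent nodal degree) + noise``; its generating
    metric value is recorded in the ``latent_metric`` column. Refuses to
    overwrite an existing cohort directory unless ``force=True``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    seed = spec.seed if seed is None else int(seed)
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} already exists; pass force=True to overwrite")
    (out_dir / "series").mkdir(parents=True, exist_ok=True)

    labels = region_labels() if spec.n_regions == 116 else [f"R{i + 1}" for i in range(spec.n_regions)]
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.generate_state(4 * 2 * n_per_group, dtype=np.uint64) % (2**31 - 1)
    rng_cov = np.random.default_rng(ss.spawn(1)[0])

    rows = []
    idx = 0
    for group in ("control", "patient"):
        for j in range(n_per_group):
            s_graph, s_perturb, s_sim, s_noise = (int(s) for s in subject_seeds[4 * idx : 4 * idx + 4])
            subject_id = f"{'pat' if group == 'patient' else 'con'}{j + 1:03d}"
            if group == "patient" and spec.effect_size > 0 and spec.effect_kind == "lattice_shift":
                p_rewire = spec.rewire_prob * (1.0 - spec.effect_size)
            else:
                p_rewire = spec.rewire_prob
            adj = make_small_world_graph(spec.n_regions, spec.lattice_degree, p_rewire, seed=s_graph)
            # coupling anchored on the unperturbed graph's spectral bound so
            # per-edge strength is identical across groups
            lam_max = np.max(np.abs(np.linalg.eigvalsh(adj.astype(float))))
            coupling = spec.coupling_fraction / lam_max
            if group == "patient" and spec.effect_size > 0 and spec.effect_kind == "triangle_edges":
                adj = perturb_group_graph(adj, spec.effect_size, seed=s_perturb)
            cov = adjacency_to_covariance(adj, coupling)
            ts = simulate_timeseries(
                cov, T, tr=spec.tr_seconds, seed=s_sim, band=spec.band, subject_id=subject_id
            )
            if spec.noise_sd > 0:
                noise_rng_ts = np.random.default_rng(s_sim + 1)
                ts = ts.with_values(ts.values + spec.noise_sd * noise_rng_ts.standard_normal(ts.values.shape))
            rel = Path("series") / f"{subject_id}.tsv"
            pd.DataFrame(ts.values, columns=labels).to_csv(out_dir / rel, sep="\t", index=False, float_format="%.6f")

            latent_metric = float(adj[spec.linked_region].sum())
            noise_rng = np.random.default_rng(s_noise)
            row = {"subject_id": subject_id, "group": group, **_covariates(rng_cov)}
            row[spec.linked_score] = (
                spec.score_intercept
                + spec.score_slope * (latent_metric - spec.lattice_degree)
                + (spec.score_group_delta if group == "patient" else 0.0)
                + noise_rng.normal(0.0, spec.score_noise_sd)
            )
            row["score_recall"] = float(noise_rng.normal(20.0, 4.5))
            row["score_timed"] = float(np.clip(noise_rng.normal(58.0, 25.0), 15, 200))
            row["latent_metric"] = latent_metric
            row["series_path"] = str(rel)
            row["n_volumes"] = T
            rows.append(row)
            idx += 1

    table = pd.DataFrame(rows)
    meta = {
        "seed": int(seed),
        "n_per_group": int(n_per_group),
        "n_volumes": int(T),
        "tr_seconds": float(spec.tr_seconds),
        "n_regions": int(spec.n_regions),
        "lattice_degree": int(spec.lattice_degree),
        "rewire_prob": float(spec.rewire_prob),
        "coupling_fraction": float(spec.coupling_fraction),
        "effect_size": float(spec.effect_size),
        "effect_kind": spec.effect_kind,
        "noise_sd": float(spec.noise_sd),
        "linked_region": int(spec.linked_region),
        "linked_score": spec.linked_score,
        "score_slope": float(spec.score_slope),
        "score_noise_sd": float(spec.score_noise_sd),
    }
    table.to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return CohortManifest(table=table, root=out_dir, meta=meta)
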