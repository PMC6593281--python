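"""End-to-end orchestration: manifest + time series -> cleaned signals -> FC ->
metric curves -> AUCs -> group statistics, written as CSV tables.

Outputs (all in the run's output directory):

- ``config.yaml``            — full echoed configuration, seed included
- ``global_auc.csv``         — per-subject AUC of the 5 global metrics
- ``nodal_auc_<metric>.csv`` — per-subject, per-region AUC of each nodal metric
- ``global_curves.csv``      — group-mean global metric curves over the grid
- ``group_global.csv``       — group comparison of the 5 global AUCs
- ``group_nodal.csv``        — group comparison of 3 nodal metrics x N regions
- ``partial_corr.csv``       — partial correlations of scores vs nodal AUCs
- ``run_log.txt``            — per-stage log (seeds, timings, disconnection warnings)
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import load_node_table
from .connectivity import pearson_matrix
from .core import SparsityGrid, SubjectTimeSeries, default_grid
from .curves import GLOBAL_METRICS, NODAL_METRICS, metric_curves
from .nulls import NullEnsembleConfig
from .prep import ConfoundSet, preprocess
from .stats import adjusted_group_compare, bonferroni, partial_correlation
from .synthetic import CohortManifest

__all__ = ["RunConfig", "run_pipeline", "summarize_run"]

DEFAULT_COVARIATES = ("sex", "age_years", "education_years", "bmi")


@dataclass
class RunConfig:
    """Every knob of one pipeline run; echoed verbatim into the output directory."""

    sparsity_min: float = 0.05
    sparsity_max: float = 0.50
    sparsity_step: float = 0.01
    n_nulls: int = 100
    swaps_per_edge: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    drop_volumes: int = 10
    ranking: str = "signed"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    alpha: float = 0.05
    bonferroni_family: str = "per_metric"  # or "pooled" across all nodal tests
    compute_nodal: bool = True
    score_columns: tuple[str, ...] = ()
    seed: int = 0
    out_dir: str = "run_out"

    def grid(self) -> SparsityGrid:
        n = int(round((self.sparsity_max - self.sparsity_min) / self.sparsity_step)) + 1
        return SparsityGrid(np.round(np.linspace(self.sparsity_min, self.sparsity_max, n), 10))

    def validate(self) -> None:
        if not 0 < self.sparsity_min < self.sparsity_max < 1:
            raise ValueError("need 0 < sparsity_min < sparsity_max < 1")
        if self.sparsity_step <= 0:
            raise ValueError("sparsity_step must be positive")
        if self.n_nulls < 1 or self.swaps_per_edge < 1:
            raise ValueError("null-ensemble settings must be >= 1")
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        if self.drop_volumes < 0:
            raise ValueError("drop_volumes must be >= 0")
        if self.ranking not in ("signed", "absolute"):
            raise ValueError("ranking must be 'signed' or 'absolute'")
        if self.bonferroni_family not in ("per_metric", "pooled"):
            raise ValueError("bonferroni_family must be 'per_metric' or 'pooled'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def _prepare_subject(ts: SubjectTimeSeries, config: RunConfig) -> SubjectTimeSeries:
    drop = config.drop_volumes if ts.n_dropped == 0 else 0
    return preprocess(ts, drop=drop, low=config.band_low_hz, high=config.band_high_hz, confounds=None)


def run_pipeline(manifest: CohortManifest, config: RunConfig) -> Path:
    """Run the full analysis for every subject in the manifest.

    Returns the output directory. Any malformed subject aborts the run with
    the subject ID (and file, for column-count mismatches) in the message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    groups = manifest.groups
    n_pat = int((groups == "patient").sum())
    n_con = int((groups == "control").sum())
    if n_pat == 0 or n_con == 0:
        raise ValueError(f"manifest needs both groups (patients={n_pat}, controls={n_con})")

    grid = config.grid()
    node_table = load_node_table()
    expected_n = None
    sub_seeds = np.random.SeedSequence(config.seed).generate_state(len(manifest.table), dtype=np.uint64) % (
        2**31 - 1
    )

    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=False))
    log(f"run started; seed={config.seed}; grid={len(grid)} points; nulls={config.n_nulls}")

    all_curves = []
    t0 = time.time()
    for i, row in enumerate(manifest.table.itertuples()):
        sid = row.subject_id
        try:
            ts = manifest.series(sid)
        except Exception as exc:
            raise RuntimeError(f"subject {sid!r}: cannot read series ({exc})") from exc
        if expected_n is None:
            expected_n = ts.n_regions
            if expected_n == 116:
                region_names = node_table["abbreviation"].tolist()
            else:
                region_names = [f"R{k + 1}" for k in range(expected_n)]
        elif ts.n_regions != expected_n:
            raise RuntimeError(
                f"subject {sid!r}: file {row.series_path} has {ts.n_regions} columns, expected {expected_n}"
            )
        clean = _prepare_subject(ts, config)
        fc = pearson_matrix(clean)
        cfg = NullEnsembleConfig(config.n_nulls, config.swaps_per_edge, int(sub_seeds[i]))
        curves = metric_curves(
            fc, grid, cfg, subject_id=sid, compute_nodal=config.compute_nodal, ranking=config.ranking
        )
        n_disc = int(curves.n_infinite_pairs.sum())
        if n_disc:
            log(f"subject {sid}: {n_disc} infinite-distance pairs summed over grid (fragmentation at low sparsity)")
        all_curves.append(curves)
    log(f"per-subject metrics done in {time.time() - t0:.1f} s ({len(all_curves)} subjects)")

    # ---- per-subject AUC tables -------------------------------------------
    g_auc = pd.DataFrame(
        [{"subject_id": c.subject_id, "group": g, **c.global_auc} for c, g in zip(all_curves, groups)]
    )
    g_auc.to_csv(out / "global_auc.csv", index=False)

    nodal_auc_frames: dict[str, pd.DataFrame] = {}
    if config.compute_nodal:
        for name in NODAL_METRICS:
            mat = np.vstack([c.nodal_auc[name] for c in all_curves])
            frame = pd.DataFrame(mat, columns=region_names)
            frame.insert(0, "group", groups.to_numpy())
            frame.insert(0, "subject_id", [c.subject_id for c in all_curves])
            frame.to_csv(out / f"nodal_auc_{name}.csv", index=False)
            nodal_auc_frames[name] = frame

    # ---- group-mean curves -------------------------------------------------
    rows = []
    for gname in ("patient", "control"):
        mask = (groups == gname).to_numpy()
        for metric in GLOBAL_METRICS:
            mean_curve = np.vstack([c.global_curves[metric] for c, m in zip(all_curves, mask) if m]).mean(axis=0)
            for sp, val in zip(grid.values, mean_curve):
                rows.append({"group": gname, "metric": metric, "sparsity": sp, "value": val})
    pd.DataFrame(rows).to_csv(out / "global_curves.csv", index=False)

    # ---- group statistics --------------------------------------------------
    covs = [c for c in config.covariates if c in manifest.table.columns]
    cov_df = manifest.table[list(covs)] if covs else None

    glob_rows = []
    for metric in GLOBAL_METRICS:
        res = adjusted_group_compare(g_auc[metric].to_numpy(), groups.to_numpy(), cov_df, metric=metric)
        glob_rows.append(
            {"metric": metric, "t": res.statistic, "df": res.df, "p": res.p, "covariates": ",".join(res.covariates)}
        )
    glob_table = pd.DataFrame(glob_rows)
    adj, rej = bonferroni(glob_table["p"].to_numpy(), alpha=config.alpha)
    glob_table["p_bonferroni"] = adj
    glob_table["significant"] = rej
    glob_table.to_csv(out / "group_global.csv", index=False)

    if config.compute_nodal:
        nodal_rows = []
        for name in NODAL_METRICS:
            frame = nodal_auc_frames[name]
            for region in region_names:
                res = adjusted_group_compare(frame[region].to_numpy(), groups.to_numpy(), cov_df, metric=region)
                nodal_rows.append({"metric": name, "region": region, "t": res.statistic, "p": res.p})
        nodal_table = pd.DataFrame(nodal_rows)
        if config.bonferroni_family == "per_metric":  # family = regions within each metric
            parts = []
            for name in NODAL_METRICS:
                sub = nodal_table[nodal_table["metric"] == name].copy()
                adj, rej = bonferroni(sub["p"].to_numpy(), alpha=config.alpha)
                sub["p_bonferroni"] = adj
                sub["significant"] = rej
                parts.append(sub)
            nodal_table = pd.concat(parts, ignore_index=True)
        else:  # pooled: one family over all metrics x regions
            adj, rej = bonferroni(nodal_table["p"].to_numpy(), alpha=config.alpha)
            nodal_table["p_bonferroni"] = adj
            nodal_table["significant"] = rej
        log(f"nodal Bonferroni family: {config.bonferroni_family}")
        nodal_table.to_csv(out / "group_nodal.csv", index=False)

    # ---- partial correlations ---------------------------------------------
    score_cols = [c for c in config.score_columns if c in manifest.table.columns]
    if not score_cols:
        score_cols = [c for c in manifest.table.columns if c.startswith("score_")]
    pc_rows = []
    if config.compute_nodal and score_cols:
        pat_mask = (groups == "patient").to_numpy()
        z = cov_df.copy() if cov_df is not None else None
        if z is not None:
            for c in z.columns:
                if z[c].dtype == object:
                    z[c] = pd.factorize(z[c])[0]
            z = z.loc[pat_mask]
        for score in score_cols:
            y = manifest.table.loc[pat_mask, score].to_numpy(dtype=float)
            for name in NODAL_METRICS:
                frame = nodal_auc_frames[name]
                for region in region_names:
                    x = frame.loc[pat_mask, region].to_numpy(dtype=float)
                    try:
                        r, p = partial_correlation(x, y, z)
                    except ValueError:
                        continue
                    pc_rows.append({"score": score, "metric": name, "region": region, "r": r, "p": p})
    pd.DataFrame(pc_rows, columns=["score", "metric", "region", "r", "p"]).to_csv(
        out / "partial_corr.csv", index=False
    )

    log(f"total wall time {time.time() - t0:.1f} s")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out


def summarize_run(run_dir: str | Path) -> str:
    """Human-readable digest of a completed run."""
    run_dir = Path(run_dir)
    lines = []
    gpath = run_dir / "group_global.csv"
    if not gpath.exists():
        raise FileNotFoundError(f"{gpath} not found; is {run_dir} a completed run?")
    glob = pd.read_csv(gpath)
    lines.append("Global AUC group comparison (patient vs control):")
    for _, r in glob.iterrows():
        mark = " *" if bool(r.get("significant", False)) else ""
        lines.append(f"  {r['metric']:<8} t={r['t']:+.3f}  p={r['p']:.4f}{mark}")
    npath = run_dir / "group_nodal.csv"
    if npath.exists():
        nod = pd.read_csv(npath)
        valid_regions = set(load_node_table()["abbreviation"])
        lines.append("Nodal AUC comparisons:")
        for metric, sub in nod.groupby("metric"):
            n_sig_raw = int((sub["p"] < 0.05).sum())
            n_sig = int(sub["significant"].sum())
            lines.append(f"  {metric:<12} {n_sig_raw} regions p<0.05 uncorrected; {n_sig} survive Bonferroni")
            top = sub.reindex(sub["t"].abs().sort_values(ascending=False).index).head(3)
            for _, r in top.iterrows():
                region = r["region"]
                tag = region if (region in valid_regions or not region.startswith("R")) else region
                lines.append(f"    {tag:<12} t={r['t']:+.3f}  p={r['p']:.4f}")
    return "\n".join(lines)
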