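"""Synthetic-cohort generator: latent graphs, covariance mapping, simulation, manifests."""

import numpy as np
import pandas as pd
import pytest

from topofc import (
    GroundTruthSpec,
    adjacency_to_covariance,
    clustering,
    generate_cohort,
    make_small_world_graph,
    pearson_matrix,
    perturb_group_graph,
    simulate_timeseries,
    sparsity_binarize,
)
from topofc.stats import partial_correlation

from conftest import ring_lattice
from oracles import bf_char_path, bf_clustering


class TestSmallWorldGraph:
    def test_ring_lattice_closed_form_clustering(self):
        a = make_small_world_graph(20, 4, 0.0, seed=0)
        assert np.array_equal(a, ring_lattice(20, 4))
        assert clustering(a)[1] == pytest.approx(3 * (4 - 2) / (4 * (4 - 1)))

    def test_ring_lattice_path_length_matches_bfs_oracle(self):
        a = make_small_world_graph(20, 4, 0.0, seed=0)
        from topofc import characteristic_path_length

        assert characteristic_path_length(a)[0] == pytest.approx(bf_char_path(a))

    @pytest.mark.parametrize("p", [0.0, 0.1, 0.5, 1.0])
    def test_edge_count_preserved_by_rewiring(self, p):
        a = make_small_world_graph(30, 6, p, seed=3)
        assert int(a.sum()) // 2 == 30 * 6 // 2
        assert np.all(np.diag(a) == 0)
        assert np.array_equal(a, a.T)

    def test_seed_reproducibility(self):
        a = make_small_world_graph(25, 4, 0.3, seed=11)
        b = make_small_world_graph(25, 4, 0.3, seed=11)
        assert np.array_equal(a, b)
        c = make_small_world_graph(25, 4, 0.3, seed=12)
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("n,k,p", [(10, 3, 0.1), (10, 10, 0.1), (10, 4, 1.5), (3, 2, 0.1)])
    def test_invalid_arguments(self, n, k, p):
        with pytest.raises(ValueError):
            make_small_world_graph(n, k, p, seed=0)


class TestPerturbation:
    def test_zero_effect_is_identity(self):
        a = make_small_world_graph(20, 4, 0.2, seed=1)
        assert np.array_equal(perturb_group_graph(a, 0.0, seed=0), a)

    def test_ring_lattice_clustering_increases(self):
        a = ring_lattice(20, 4)
        out = perturb_group_graph(a, 0.2, seed=2)
        assert clustering(out)[1] >= 0.5
        assert int(out.sum()) // 2 == 40 + round(0.2 * 40)

    def test_clustering_never_decreases_on_ws_graphs(self):
        for s in range(5):
            a = make_small_world_graph(30, 6, 0.15, seed=s)
            out = perturb_group_graph(a, 0.2, seed=s)
            assert bf_clustering(out)[1] >= bf_clustering(a)[1] - 1e-12

    def test_complete_graph_rejected(self):
        a = np.ones((6, 6), dtype=np.uint8)
        np.fill_diagonal(a, 0)
        with pytest.raises(ValueError, match="closable"):
            perturb_group_graph(a, 0.3, seed=0)


class TestCovarianceMapping:
    def test_zero_coupling_gives_identity(self):
        a = ring_lattice(10, 4)
        assert np.allclose(adjacency_to_covariance(a, 0.0), np.eye(10))

    def test_positive_definite(self):
        a = make_small_world_graph(30, 6, 0.2, seed=5)
        lam = np.max(np.abs(np.linalg.eigvalsh(a.astype(float))))
        cov = adjacency_to_covariance(a, 0.8 / lam)
        assert np.linalg.eigvalsh(cov).min() > 0
        assert np.allclose(np.diag(cov), 1.0)

    def test_adjacent_pairs_correlate_more_than_distant(self):
        a = ring_lattice(20, 4)
        cov = adjacency_to_covariance(a, 0.1)
        from topofc import shortest_path_lengths

        d = shortest_path_lengths(a)
        off = ~np.eye(20, dtype=bool)
        assert cov[off & (d == 1)].min() > cov[off & (d >= 3)].max()

    def test_spectral_bound_enforced(self):
        a = ring_lattice(12, 4)
        with pytest.raises(ValueError, match="spectral bound"):
            adjacency_to_covariance(a, 0.3)  # lambda_max = 4 -> bound 0.25


class TestSimulation:
    def test_identity_covariance_uncorrelated(self):
        ts = simulate_timeseries(np.eye(10), T=10000, seed=0, band=None)
        r = np.corrcoef(ts.values, rowvar=False)
        off = ~np.eye(10, dtype=bool)
        assert np.abs(r[off]).mean() < 0.05

    def test_parameter_recovery_long_series(self):
        a = ring_lattice(20, 4)
        cov = adjacency_to_covariance(a, 0.2)
        ts = simulate_timeseries(cov, T=2000, seed=1, band=None)
        r = np.corrcoef(ts.values, rowvar=False)
        off = np.triu_indices(20, 1)
        assert np.corrcoef(r[off], cov[off])[0, 1] > 0.9

    def test_band_limiting_preserves_correlation_structure(self):
        a = ring_lattice(16, 4)
        cov = adjacency_to_covariance(a, 0.2)
        ts = simulate_timeseries(cov, T=4000, seed=2, band=(0.01, 0.08))
        r = np.corrcoef(ts.values, rowvar=False)
        off = np.triu_indices(16, 1)
        assert np.corrcoef(r[off], cov[off])[0, 1] > 0.85

    def test_seed_determinism_and_pd_check(self):
        cov = adjacency_to_covariance(ring_lattice(8, 2), 0.3)
        a = simulate_timeseries(cov, T=100, seed=5)
        b = simulate_timeseries(cov, T=100, seed=5)
        assert np.array_equal(a.values, b.values)
        with pytest.raises(ValueError, match="positive definite"):
            simulate_timeseries(np.ones((4, 4)), T=100, seed=0)

    def test_topology_recovery_at_true_density(self):
        """Binarizing long-series sample FC at the true edge density recovers
        most ground-truth edges (n <= 50 nodes)."""
        a = make_small_world_graph(40, 6, 0.1, seed=9)
        lam = np.max(np.abs(np.linalg.eigvalsh(a.astype(float))))
        cov = adjacency_to_covariance(a, 0.7 / lam)
        ts = simulate_timeseries(cov, T=2000, seed=9, band=None)
        fc = pearson_matrix(ts)
        density = a.sum() / (40 * 39)
        g = sparsity_binarize(fc, density)
        overlap = int((g.adjacency & a).sum()) / int(a.sum())
        assert overlap > 0.8


class TestCohort:
    def test_manifest_shape_and_groups(self, tiny_cohort):
        t = tiny_cohort.table
        assert len(t) == 10
        assert (t["group"] == "patient").sum() == 5
        assert (t["group"] == "control").sum() == 5
        for col in ("age_years", "education_years", "bmi", "score_moca", "latent_metric"):
            assert np.isfinite(t[col]).all()
        for sid in t["subject_id"]:
            ts = tiny_cohort.series(sid)
            assert ts.n_timepoints == 70
            assert ts.n_regions == 12

    def test_refuses_overwrite(self, tiny_cohort):
        spec = GroundTruthSpec(n_regions=12, lattice_degree=4, seed=7)
        with pytest.raises(FileExistsError):
            generate_cohort(spec, n_per_group=2, T=60, out_dir=tiny_cohort.root)

    def test_seed_changes_series_not_schema(self, tmp_path):
        spec = GroundTruthSpec(n_regions=10, lattice_degree=4, seed=0)
        m1 = generate_cohort(spec, n_per_group=2, T=60, seed=1, out_dir=tmp_path / "a")
        m2 = generate_cohort(spec, n_per_group=2, T=60, seed=2, out_dir=tmp_path / "b")
        assert list(m1.table.columns) == list(m2.table.columns)
        s1 = m1.series(m1.table["subject_id"].iloc[0]).values
        s2 = m2.series(m2.table["subject_id"].iloc[0]).values
        assert not np.allclose(s1, s2)

    def test_noiseless_score_link_recovers_exactly(self, tmp_path):
        spec = GroundTruthSpec(
            n_regions=16, lattice_degree=4, rewire_prob=0.3, score_noise_sd=0.0, seed=3
        )
        man = generate_cohort(spec, n_per_group=15, T=60, seed=3, out_dir=tmp_path / "c")
        t = man.table
        group = (t["group"] == "patient").to_numpy(float)
        r, _ = partial_correlation(
            t["latent_metric"].to_numpy(), t["score_moca"].to_numpy(), group[:, None]
        )
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_score_link_recovery_with_noise(self, tmp_path):
        """Across replicate cohorts the manifest's score-metric correlation
        scatters around the generating value implied by slope and noise SD."""
        rs = []
        rho_true = []
        for rep in range(10):
            spec = GroundTruthSpec(
                n_regions=16, lattice_degree=4, rewire_prob=0.3, score_noise_sd=1.0, seed=rep
            )
            man = generate_cohort(spec, n_per_group=15, T=60, seed=rep, out_dir=tmp_path / f"r{rep}")
            t = man.table
            group = (t["group"] == "patient").to_numpy(float)
            r, _ = partial_correlation(
                t["latent_metric"].to_numpy(), t["score_moca"].to_numpy(), group[:, None]
            )
            rs.append(r)
            sd_m = t["latent_metric"].std(ddof=1)
            signal = spec.score_slope * sd_m
            rho_true.append(signal / np.hypot(signal, spec.score_noise_sd))
        # mean recovered r within 3 SEM of the mean generating correlation
        rs, rho_true = np.array(rs), np.array(rho_true)
        sem = rs.std(ddof=1) / np.sqrt(len(rs))
        assert abs(rs.mean() - rho_true.mean()) < 3 * sem + 0.05
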