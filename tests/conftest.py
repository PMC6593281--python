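import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from topofc import GroundTruthSpec, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


def k4():
    a = np.ones((4, 4), dtype=np.uint8)
    np.fill_diagonal(a, 0)
    return a


def star(n_leaves=4):
    a = np.zeros((n_leaves + 1, n_leaves + 1), dtype=np.uint8)
    a[0, 1:] = 1
    a[1:, 0] = 1
    return a


def ring_lattice(n, k):
    a = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for d in range(1, k // 2 + 1):
            a[i, (i + d) % n] = a[(i + d) % n, i] = 1
    return a


def random_graph(n, p, seed):
    g = np.random.default_rng(seed)
    a = (g.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, 1)
    return a + a.T


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """Small but complete cohort: 12 regions, 5 per group, 70 volumes."""
    spec = GroundTruthSpec(
        n_regions=12, lattice_degree=4, coupling_fraction=0.7, noise_sd=0.3, seed=7
    )
    out = tmp_path_factory.mktemp("cohort")
    return generate_cohort(spec, n_per_group=5, T=70, seed=7, out_dir=out, force=True)
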