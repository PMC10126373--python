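import numpy as np
import pytest

import motioncpm as mc


@pytest.fixture
def cfg():
    return mc.RunConfig(rng_seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def _planted_spec(seed: int) -> mc.SyntheticSpec:
    n_nodes = 30
    n_edges = n_nodes * (n_nodes - 1) // 2
    picker = np.random.default_rng(99)
    planted = tuple(sorted(picker.choice(n_edges, 40, replace=False).tolist()))
    return mc.SyntheticSpec(n_subjects=60, n_nodes=n_nodes, n_frames=150,
                            coupling_edges=planted, coupling_strength=0.5,
                            artifact_gain=0.0, seed=seed)


@pytest.fixture(scope="session")
def planted_cohort():
    """A small cohort with strong motion-coupled edges (shared across tests)."""
    return mc.simulate_cohort(_planted_spec(seed=21))


@pytest.fixture(scope="session")
def planted_edges(planted_cohort):
    cfg = mc.RunConfig(rng_seed=0)
    return mc.cohort_edge_matrix(planted_cohort, cfg)
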