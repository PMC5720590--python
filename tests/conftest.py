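import numpy as np
import pytest

from allomsm.structure import ProbePair, ReferenceStructure
from allomsm.synthetic import GeneratorConfig, base_geometry, make_default_topology


@pytest.fixture(scope="session")
def topology():
    """Default two-chain backbone topology (A 400-460, B 440-480)."""
    return make_default_topology(61, 41)


@pytest.fixture(scope="session")
def reference(topology):
    return ReferenceStructure(
        topology=topology,
        coords=base_geometry(topology),
        probe=ProbePair("A", 427, "B", 477),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One desk-scale generated dataset shared across tests (seed frozen)."""
    from allomsm.synthetic import make_variant_pair

    config = GeneratorConfig.small_preset(seed=7)
    trajectories, ref, truth = make_variant_pair(config)
    return config, trajectories, ref, truth


def random_coords(rng: np.random.Generator, n: int, scale: float = 5.0) -> np.ndarray:
    """Non-degenerate random 3-D point cloud."""
    while True:
        x = rng.normal(scale=scale, size=(n, 3))
        s = np.linalg.svd(x - x.mean(0), compute_uv=False)
        if s[1] > 1e-3:
            return x
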