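import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vpdp import PointCloud, make_standard_scene

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

SCENE_SEED = 1


@pytest.fixture(scope="session")
def scene():
    """The standard synthetic study: stand, two platform scans, satellite image."""
    return make_standard_scene(seed=SCENE_SEED)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_cloud(rng):
    """1000 points in a 30 x 20 x 15 m box."""
    pts = rng.uniform([0, 0, 0], [30, 20, 15], (1000, 3))
    return PointCloud(pts)


def random_voxel_grid(rng, dims=(10, 10, 10), density=0.3, max_count=9):
    """Sparse random count grid for oracle comparisons."""
    from vpdp import VoxelGrid

    counts = rng.integers(1, max_count + 1, dims) * (rng.random(dims) < density)
    return VoxelGrid((0.0, 0.0, 0.0), 0.5, counts.astype(np.int64))
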