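import numpy as np
import pytest

from lodgepoint.pointcloud import PointCloud
from lodgepoint.synthetic import FieldSimConfig, generate_plot


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_plot():
    """A moderately lodged synthetic plot with truth record (session cache)."""
    cfg = FieldSimConfig(point_density=300, seed=7)
    cloud, truth = generate_plot(cfg, theta=53.0, LR=0.5, rng=np.random.default_rng(7))
    return cfg, cloud, truth


@pytest.fixture
def random_cloud(rng):
    coords = rng.normal(size=(200, 3)) * np.array([3.0, 1.5, 0.2]) + np.array([10.0, -4.0, 55.0])
    return PointCloud(coords)
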