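import numpy as np
import pytest

from understory import PlotGeometry, PointCloud


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def default_geom():
    return PlotGeometry(center_x=13.5, center_y=13.5)


def make_cloud(rng, n, x_range=(0.0, 27.0), y_range=(0.0, 27.0),
               z_range=(0.5, 15.5)):
    """Uniform random cloud helper used across modules."""
    return PointCloud(
        rng.uniform(*x_range, n),
        rng.uniform(*y_range, n),
        rng.uniform(*z_range, n),
        np.ones(n, dtype=np.int64),
        np.ones(n, dtype=np.int64),
    )


@pytest.fixture()
def clipped_cloud(rng, default_geom):
    # strictly inside the default plot box
    return make_cloud(rng, 5000, (1e-6, 27 - 1e-6), (1e-6, 27 - 1e-6),
                      (0.5, 15.5 - 1e-6))
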