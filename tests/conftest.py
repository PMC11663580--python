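import numpy as np
import pytest

from hullseg import fixtures as fx


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture(scope="session")
def small_series():
    """Separable, noiseless fixture series: 2 groups x 2x2 units, 4 timepoints."""
    spec = fx.FixtureSpec(
        seed=7, rows=2, cols=2, groups=2, n_timepoints=4, noise_sigma=0.0
    )
    return fx.make_image_series(spec)


def random_cloud(rng, n, spread=30.0, center=None):
    """Random Lab-ish point cloud, guaranteed full affine rank."""
    if center is None:
        center = rng.uniform(20, 70, size=3)
    while True:
        pts = center + rng.normal(0, spread / 3, size=(n, 3))
        if np.linalg.matrix_rank(pts - pts.mean(axis=0)) == 3:
            return pts
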