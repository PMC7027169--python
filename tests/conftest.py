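import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from emlddmm.grids import Image, ImageGrid


@pytest.fixture
def grid2d():
    return ImageGrid((8, 6), (1.0, 2.0), (0.0, -1.0))


@pytest.fixture
def smooth_image():
    """Smooth random scalar image on a unit-spaced 16x16 grid."""
    rng = np.random.default_rng(0)
    g = ImageGrid((16, 16), (1.0, 1.0), (0.0, 0.0))
    vals = gaussian_filter(rng.normal(size=(16, 16)), 2.5, mode="wrap")
    return Image(g, vals)


def make_texture(n=96, sigma=3.0, seed=5, spacing=1.0):
    rng = np.random.default_rng(seed)
    g = ImageGrid((n, n), (spacing, spacing), (0.0, 0.0))
    vals = gaussian_filter(rng.normal(size=(n, n)), sigma)
    vals = (vals - vals.mean()) / vals.std()
    return Image(g, vals)


@pytest.fixture(scope="session")
def phantom_em_metrics():
    """One full EM registration of the simulated phantom, shared by the
    monotonicity, posterior-recovery, contrast-recovery and diffeomorphism
    tests."""
    from emlddmm.experiments import phantom_em_experiment

    return phantom_em_experiment(seed=0)
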