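import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from vpiradiomics import VOI

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_voi(rng):
    """A small noisy VOI with a box mask — generic texture input."""
    img = rng.normal(-500.0, 120.0, (8, 16, 16))
    mask = np.zeros((8, 16, 16), dtype=bool)
    mask[2:6, 4:12, 4:12] = True
    return VOI(img, mask, spacing=(1.0, 1.0, 1.0), case_id="rand")


@pytest.fixture
def ball_voi():
    """A digital ball of radius 8 voxels inside a 24³ grid."""
    shape = (24, 24, 24)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    c = 11.5
    mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= 8.0 ** 2
    img = np.full(shape, -700.0)
    img[mask] = -100.0
    return VOI(img, mask, spacing=(1.0, 1.0, 1.0), case_id="ball")


def make_voi(values_3d, mask=None, spacing=(1.0, 1.0, 1.0)):
    arr = np.asarray(values_3d, dtype=float)
    if mask is None:
        mask = np.ones(arr.shape, dtype=bool)
    return VOI(arr, mask, spacing=spacing)
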