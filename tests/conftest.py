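import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(autouse=True)
def _quiet_sample_floor():
    """Synthetic samples are intentionally far below the 200-nuclei floor."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="sample holds")
        yield


@pytest.fixture
def disk_plane():
    """A single bright disk of radius 8 at (50, 50) on a dark background."""
    from skimage.draw import disk

    from nucleoscan import ImagePlane

    img = np.zeros((100, 100))
    rr, cc = disk((50, 50), 8)
    img[rr, cc] = 0.8
    return ImagePlane(img)
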