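import numpy as np
import pytest

from interfish.imaging_core import MultiChannelImage, NucleusMask
from interfish.synthetic_fixtures import SimulationConfig, generate_field_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_image(rng):
    """A 64x64 two-channel image with one centered square nucleus label."""
    px = rng.integers(0, 256, size=(64, 64, 2), dtype=np.uint8)
    image = MultiChannelImage(
        pixels=px, channel_names=("dapi", "target"), image_id="fixture"
    )
    labels = np.zeros((64, 64), dtype=np.int32)
    labels[10:50, 10:50] = 1
    return image, NucleusMask(labels=labels)


@pytest.fixture(scope="session")
def synthetic_field():
    """One deterministic mixed-class field image with ground truth."""
    config = SimulationConfig(n_nuclei=9, seed=7, class_mixture=(0.4, 0.3, 0.3))
    return generate_field_image(config)


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
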