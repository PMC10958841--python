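import numpy as np
import pytest

from nucleodyn.synthetic import gen_nucleus_mask


@pytest.fixture(scope="session")
def disk_mask_100():
    """Disk of radius 100 px (10 um at 100 nm/px) in a 256x256 frame."""
    return gen_nucleus_mask(256, 256, 100.0, (10_000.0, 10_000.0))


@pytest.fixture(scope="session")
def disk_mask_50():
    """Disk of radius 50 px (5 um at 100 nm/px) in a 128x128 frame."""
    return gen_nucleus_mask(128, 128, 100.0, (5_000.0, 5_000.0))


@pytest.fixture(scope="session")
def small_mask():
    """Small disk (radius 25 px) for pixel-heavy cube tests."""
    return gen_nucleus_mask(64, 64, 100.0, (2_500.0, 2_500.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
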