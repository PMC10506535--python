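import numpy as np
import pytest

from ramanstain import phantom
from ramanstain.preprocess import PatchRecord


@pytest.fixture(scope="session")
def axis():
    return phantom.make_axis()


@pytest.fixture(scope="session")
def library(axis):
    return phantom.make_spectral_library(0, axis)


@pytest.fixture(scope="session")
def small_sample():
    """One 64×64 phantom sample shared across read-only tests."""
    return phantom.generate_sample(7, shape=(64, 64), grade_class="moderate")


@pytest.fixture(scope="session")
def patch_pairs():
    """Eight 64×64 phantom SRS/H&E pairs for training smokes."""
    pairs = []
    for i in range(8):
        s = phantom.generate_sample(i, shape=(64, 64),
                                    grade_class=["low", "moderate", "high"][i % 3])
        pairs.append(PatchRecord(s.bands, s.ff_he, (0, 0), f"s{i}"))
    return pairs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
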