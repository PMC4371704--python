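import numpy as np
import pytest

from eegspike import EegSegment, normalize_segment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_segment(rng):
    """A normalized 4096-sample white-noise segment."""
    return normalize_segment(EegSegment(rng.standard_normal(4096)))


@pytest.fixture
def short_noise(rng):
    """A normalized 512-sample white-noise segment (fast paths)."""
    return normalize_segment(EegSegment(rng.standard_normal(512)))
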