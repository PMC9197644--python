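import numpy as np
import pytest

from ielm.bands import RawSegment
from ielm.synthetic import generate_feature_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_segment():
    """10 s, 256 Hz, pure 10 Hz alpha sine."""
    fs = 256.0
    t = np.arange(int(10 * fs)) / fs
    return RawSegment("sine10", np.sin(2 * np.pi * 10 * t), fs, label="low")


@pytest.fixture
def noise_segment(rng):
    fs = 256.0
    return RawSegment("noise", rng.standard_normal(int(10 * fs)), fs)


@pytest.fixture(scope="session")
def imbalanced_table():
    """Stratified imbalanced feature fixture shared by classifier tests."""
    return generate_feature_dataset(300, proportions=(0.42, 0.46, 0.12), seed=7)
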