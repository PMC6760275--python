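import numpy as np
import pytest

from cardioscreen.sim import HeartSimParams, simulate_heart_video


@pytest.fixture(scope="session")
def small_heart():
    """A short (8 s) regular 150 bpm heart video with its ground truth."""
    params = HeartSimParams(ventricular_bpm=150, duration=8.0, seed=12345)
    return simulate_heart_video(params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
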