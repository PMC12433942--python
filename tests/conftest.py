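import numpy as np
import pytest

from emgsyn import make_ground_truth, synthesize_subject
from emgsyn.preprocess import average_trials, preprocess_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def model_r3():
    """Well-separated 3-synergy ground truth over the 14 canonical muscles."""
    return make_ground_truth(3, 14, seed=7)


@pytest.fixture(scope="session")
def model_r4():
    return make_ground_truth(4, 14, seed=42)


@pytest.fixture(scope="session")
def noisy_envelope(model_r3):
    """One subject's time-normalized, MVC-normalized envelope (14×200)."""
    rec = synthesize_subject(model_r3, noise_sd=0.05, seed=11)
    return preprocess_recording(rec).values


@pytest.fixture
def subject_envelope_factory():
    """Preprocess-and-average helper for a list of trial recordings."""

    def _make(trials, **kw):
        return average_trials([preprocess_recording(t, **kw) for t in trials])

    return _make
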