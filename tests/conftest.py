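import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from aadloop.listener import ListenerModel
from aadloop.session import SessionConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def quick_config():
    """Scaled-down session for fast orchestration tests."""
    return SessionConfig(
        n_training_trials=4,
        n_feedback_phase_trials=10,
        trial_length_s=30.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def clean_listener():
    """High-contrast, noiseless listener: decoding should be essentially
    perfect, making pipeline defects visible."""
    return ListenerModel.create(seed=5, g_att=1.0, g_una=0.3, noise_sigma=0.0)


@pytest.fixture(scope="session")
def noisy_listener():
    """Listener at the default realistic operating point."""
    return ListenerModel.create(seed=3)
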