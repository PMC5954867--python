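import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eegfatigue as ef

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_alert_record():
    """30 s fully-alert session at 256 Hz, band-structured."""
    cfg = ef.SimConfig(duration=30.0, sampling_rate=256.0, seed=7)
    record, labels = ef.simulate_eeg(cfg)
    return record


@pytest.fixture(scope="session")
def alert_feature_matrix():
    """Feature rows from a 2-minute alert session (60 epochs)."""
    cfg = ef.SimConfig(duration=120.0, seed=42)
    record, _ = ef.simulate_eeg(cfg)
    epochs = ef.epoch_stream(record, 2.0)
    return ef.extract_features(epochs, record.sfreq)
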