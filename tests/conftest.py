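import numpy as np
import pytest

from effortdecode import SessionConfig, build_features, generate_session
from effortdecode.types import FeatureMatrix


@pytest.fixture(scope="session")
def small_session():
    """One compact synthetic session: 8 channels at 100 Hz, 1 block of 2 s
    segments (34 s total)."""
    cfg = SessionConfig(n_eeg_channels=8, eeg_rate=100.0, marg_rate=128.0,
                        n_trial_blocks=1, segment_duration_s=2.0, seed=7)
    eeg, marg, schedule = generate_session(cfg)
    return cfg, eeg, marg, schedule


@pytest.fixture(scope="session")
def separable_classes():
    """Three well-separated Gaussian classes in 5 dimensions (n=300)."""
    rng = np.random.default_rng(42)
    means = np.array([[0, 0, 0, 0, 0], [8, 8, 0, 0, 0], [0, 8, 8, 0, 0]],
                     dtype=float)
    X = np.vstack([rng.normal(m, 1.0, size=(100, 5)) for m in means])
    y = np.repeat(["a", "b", "c"], 100)
    return X, y


def make_feature_matrix(X, y, n_channels=1, l=None, rate=100.0):
    """Wrap a plain (X, y) pair as a FeatureMatrix for the evaluators."""
    n, d = X.shape
    if l is None:
        l = d // n_channels
    labels = [f"ch{i}" for i in range(n_channels)]
    return FeatureMatrix(X=X, y=np.asarray(y, dtype=object),
                         row_time=np.arange(n) / rate,
                         channel_labels=labels, l=l, rate=rate)


@pytest.fixture(scope="session")
def separable_fm(separable_classes):
    X, y = separable_classes
    return make_feature_matrix(X, y, n_channels=5, l=1)
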