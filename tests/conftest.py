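import warnings

import numpy as np
import pytest
from sklearn.exceptions import ConvergenceWarning

from crossmi import SynthConfig, build_toy_headmodel, simulate_subject_pair
from crossmi.preprocess import bandpass, window_trials

warnings.filterwarnings("ignore", category=ConvergenceWarning)


@pytest.fixture(scope="session")
def head32():
    """Small test-scale forward model (32 electrodes / 200 sources)."""
    return build_toy_headmodel(32, 200, rng_seed=7)


@pytest.fixture(scope="session")
def head16():
    """Tiny forward model for fast unit tests."""
    return build_toy_headmodel(16, 60, rng_seed=3)


@pytest.fixture(scope="session")
def pair32(head32):
    """One preprocessed associative subject pair at SNR 10 (20 trials/class)."""
    cfg = SynthConfig(
        n_trials_per_class=20, rng_seed=11, target_snr=10.0, shared_fraction=1.0
    )
    X, Y = simulate_subject_pair(head32, cfg)
    return window_trials(bandpass(X)), window_trials(bandpass(Y)), cfg


def jaccard(a, b) -> float:
    a, b = set(np.asarray(a).tolist()), set(np.asarray(b).tolist())
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
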