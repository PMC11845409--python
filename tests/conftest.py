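import numpy as np
import pytest

from stridelock.simulate import (EEGSimParams, SaccadeSimParams,
                                 WalkSimParams, simulate_gaze, simulate_walk)


@pytest.fixture(scope="session")
def natural_walk():
    """20-trial natural-speed walk with ground truth (shared, read-only)."""
    params = WalkSimParams.for_condition("natural", n_trials=20)
    return simulate_walk(params, seed=1234)


@pytest.fixture(scope="session")
def gaze_session(natural_walk):
    """Walk plus a modulated saccade train and its truth table."""
    rec, truth = natural_walk
    rec2, sacc = simulate_gaze(
        rec, truth,
        SaccadeSimParams(modulation_depth=0.3, amplitude_min=1.0,
                         min_isi=0.15),
        seed=77)
    return rec2, truth, sacc


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
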