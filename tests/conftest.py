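import logging

import numpy as np
import pytest

import synergait as sg

logging.getLogger("synergait").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_gt():
    """40-stride ground truth with a short lead-in (trim 5 s in tests)."""
    return sg.make_ground_truth(n_strides=40, lead_in=5.0, seed=2)


@pytest.fixture(scope="session")
def small_trial(small_gt):
    return sg.gen_trial(small_gt, sg.TrialMeta("S01", "Pre", "narrow"),
                        include_emg=True, snr_db=20.0)


@pytest.fixture(scope="session")
def trimmed_trial(small_trial):
    return sg.trim_initial(small_trial, 5.0)


@pytest.fixture(scope="session")
def small_events(trimmed_trial):
    return sg.detect_events(trimmed_trial)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
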