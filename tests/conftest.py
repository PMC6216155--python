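import numpy as np
import pytest

from synergia import make_ground_truth, synthesize_trial


@pytest.fixture(scope="session")
def ground_truth():
    """Default rank-4 ground truth with moderate envelope noise."""
    return make_ground_truth(seed=7, noise_sd=0.1)


@pytest.fixture(scope="session")
def synthetic_trial(ground_truth):
    """One 30-cycle raw trial with its cycle table and true envelope."""
    return synthesize_trial(ground_truth, n_cycles=30, participant_id="P0001",
                            trial_no=1)


@pytest.fixture(scope="session")
def noise_free_trial():
    """Degenerate trial: no envelope noise, constant carrier.

    The rectified raw signal equals the modulating envelope exactly, so the
    whole conditioning chain can be checked against the generator truth.
    """
    gt = make_ground_truth(seed=11, noise_sd=0.0)
    return gt, synthesize_trial(gt, n_cycles=30, participant_id="P0002",
                                trial_no=1, carrier="constant")


@pytest.fixture(scope="session")
def clean_carrier_trial():
    """Noise-free envelope with the stochastic band-limited carrier."""
    gt = make_ground_truth(seed=11, noise_sd=0.0)
    return gt, synthesize_trial(gt, n_cycles=30, participant_id="P0003",
                                trial_no=1, carrier="bandlimited")


@pytest.fixture
def rng():
    return np.random.default_rng(123)
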