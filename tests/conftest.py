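import pytest

from pyrewash import RunConfig, SyntheticTruth, generate_campaign


@pytest.fixture(scope="session")
def noise_free_campaign():
    """Small noise-free campaign: the forward pipeline must reproduce it
    exactly (closed loop)."""
    truth = SyntheticTruth(seed=1)
    return generate_campaign(truth, n_events=15, seed=1), truth


@pytest.fixture(scope="session")
def noisy_campaign():
    """100-event campaign with sigma=0.01 observation noise, for
    parameter-recovery checks."""
    truth = SyntheticTruth(load_noise_sigma=0.01, fraction_noise_sigma=0.01, seed=1)
    return generate_campaign(truth, n_events=100, seed=1), truth


@pytest.fixture(scope="session")
def noisy_config(noisy_campaign):
    _, truth = noisy_campaign
    return RunConfig.from_truth(truth)
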