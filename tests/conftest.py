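import numpy as np
import pytest

import canegait as cg


@pytest.fixture(scope="session")
def profiles():
    return cg.default_profiles()


@pytest.fixture(scope="session")
def control_profile(profiles):
    return profiles["control"]


@pytest.fixture(scope="session")
def clean_trial(control_profile):
    """Noise-free 10-stride control trial (cane, shank, truth)."""
    cfg = cg.StudyConfig(n_participants=1, strides_per_trial=10, seed=0,
                         noise_sd_strain=0.0, noise_sd_gyro=0.0)
    return cg.generate_trial(control_profile, cfg, seed=11)


@pytest.fixture(scope="session")
def noisy_trial(control_profile):
    """Default-noise 10-stride control trial."""
    cfg = cg.StudyConfig(n_participants=1, strides_per_trial=10, seed=0)
    return cg.generate_trial(control_profile, cfg, seed=11)


@pytest.fixture(scope="session")
def clean_trial_result(clean_trial, control_profile):
    cane, shank, truth = clean_trial
    return cg.run_trial(cane, shank, cane_length=control_profile.cane_length_m)


@pytest.fixture(scope="session")
def noisy_trial_result(noisy_trial, control_profile):
    cane, shank, truth = noisy_trial
    return cg.run_trial(cane, shank, cane_length=control_profile.cane_length_m)
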