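import numpy as np
import pytest
from dataclasses import replace

from gaitevents.synthetic_gait import PRESET_PROFILES, CohortSpec, simulate_cohort, simulate_trial


@pytest.fixture(scope="session")
def heel_profile_clean():
    """Heel-strike persona with noise disabled (exact construction checks)."""
    return replace(PRESET_PROFILES["HC-heel"], noise_sd_mm=0.0, duration_s=8.0)


@pytest.fixture(scope="session")
def heel_trial_clean(heel_profile_clean):
    return simulate_trial(heel_profile_clean, "subj-0", "trial-0", seed=7)


@pytest.fixture(scope="session")
def heel_cohort_clean(heel_profile_clean):
    """20 noise-free heel-strike trials with >= 10 gait cycles each."""
    profile = replace(heel_profile_clean, duration_s=12.0)
    spec = CohortSpec(profiles=((profile, 10, 2),), seed=3)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def forefoot_cohort_clean():
    """Noise-free forefoot-strike cohort (toe leads the heel by 60 ms)."""
    profile = replace(
        PRESET_PROFILES["ICP-forefoot"], noise_sd_mm=0.0, duration_s=12.0,
        heel_toe_offset_ms=-60.0,
    )
    spec = CohortSpec(profiles=((profile, 10, 2),), seed=3)
    return simulate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
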