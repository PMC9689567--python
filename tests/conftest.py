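import numpy as np
import pytest

from liftrisk.signal import CHANNELS, ImuRecording
from liftrisk.synth import SynthConfig, generate_cohort, generate_session, make_profile


@pytest.fixture(scope="session")
def small_synth_config() -> SynthConfig:
    """A scaled-down cohort (4 subjects, 8 lifts) for fast unit tests."""
    return SynthConfig(n_subjects=4, n_lifts=8, trial_duration_s=120.0)


@pytest.fixture(scope="session")
def small_cohort(small_synth_config):
    return generate_cohort(small_synth_config, seed=11)


@pytest.fixture(scope="session")
def one_session():
    """One default-design session (20 lifts, 5 min, 128 Hz) with truth ROIs."""
    config = SynthConfig()
    profile = make_profile("S01", config, np.random.default_rng(3))
    return generate_session(profile, "NO_RISK", config, seed=5), config


@pytest.fixture
def noise_recording():
    rng = np.random.default_rng(99)
    n = 4096
    return ImuRecording(
        subject_id="N00",
        trial_label="unknown",
        fs=128.0,
        channels={c: rng.normal(0, 0.05, n) for c in CHANNELS},
    )
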