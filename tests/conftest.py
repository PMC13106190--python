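import numpy as np
import pytest

from bradykin.preprocess import SegmentationConfig, preprocess_recording
from bradykin.simulate import SeverityProfile, generate_linear_task_signal


@pytest.fixture
def clean_profile() -> SeverityProfile:
    """Score-0 profile with every stochastic component switched off."""
    return SeverityProfile(0, base_rate=2.0, amplitude=1.0, decrement_rate=0.0,
                           hesitation_prob=0.0, tremor_amp=0.0, noise_sd=0.0)


@pytest.fixture
def clean_ft_segment(clean_profile):
    """One 4-s finger-tapping segment with unambiguous closing peaks
    (opening peaks at 0.25x, below the low-amplitude threshold)."""
    rec = generate_linear_task_signal(clean_profile, 4.0, 80.0, seed=1,
                                      opening_ratio=0.25)
    return preprocess_recording(rec, SegmentationConfig())[0]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
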