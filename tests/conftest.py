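import numpy as np
import pytest

from wavebp.synth import SynthConfig, generate_record


@pytest.fixture(scope="session")
def clean_record():
    """A 60-s noise-free synthetic subject: extrema are exact, no drift."""
    cfg = SynthConfig(duration_s=60.0, noise_sd=0.0, ppg_drift_slope=0.0, seed=7)
    rec, gt = generate_record(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def eight_min_record():
    """An 8-min synthetic subject at 125 Hz (60000 samples), default noise."""
    cfg = SynthConfig(duration_s=480.0, seed=11)
    rec, gt = generate_record(cfg)
    return cfg, rec, gt


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
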