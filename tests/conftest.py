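import numpy as np
import pytest

from pulse2abp.synth import SynthConfig, generate_segment


@pytest.fixture()
def clean_config():
    """Noise-free default-morphology segment configuration."""
    return SynthConfig(segment_len=1024, seed=7)


@pytest.fixture()
def clean_segment(clean_config):
    return generate_segment(clean_config)


@pytest.fixture()
def noisy_config():
    """Realistic acquisition: mild noise and baseline wander, 35-sample lag."""
    return SynthConfig(
        segment_len=1024, seed=5, noise_sd=0.01, baseline_wander_amp=0.05,
        lag_samples=35,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
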