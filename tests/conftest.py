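"""Shared fixtures: synthetic recordings at various noise levels."""

import numpy as np
import pytest

from cufflessbp.synth import SynthConfig, generate_recording


def clean_config(**overrides) -> SynthConfig:
    """A noiseless, jitter-free configuration for oracle-style tests."""
    base = dict(duration_s=60.0, hr_mean=60.0, hr_sd=0.0,
                ptt_amplitude=0.0, rji_sd_ms=0.0, bp_noise_sd=0.0,
                noise_wander_amp=0.0, noise_powerline_amp=0.0,
                noise_white_sd=0.0, seed=7)
    base.update(overrides)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def clean_recording():
    return generate_recording(clean_config())


@pytest.fixture(scope="session")
def default_recording():
    return generate_recording(SynthConfig(duration_s=60.0, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
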