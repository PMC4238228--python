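import numpy as np
import pytest
from hypothesis import settings

from semgkit.synth import SynthConfig, generate_recording

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """Fast 4-class session: 8 bursts of 0.8 s separated by 1 s of rest."""
    return SynthConfig(
        reps_per_class=2, burst_duration=0.8, rest_duration=1.0, seed=11
    )


@pytest.fixture(scope="session")
def small_recording(small_config):
    return generate_recording(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
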