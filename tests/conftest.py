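import numpy as np
import pytest

from respiradar import BreathProfile, preprocess, simulate_respiration


@pytest.fixture(scope="session")
def default_profile():
    return BreathProfile()  # 15 bpm, 5 mm, mild jitter


@pytest.fixture(scope="session")
def calm_wave(default_profile):
    """10 minutes of undisturbed breathing at the default profile."""
    return simulate_respiration(default_profile, 600.0, fs=20.0, seed=1)


@pytest.fixture(scope="session")
def calm_clean(calm_wave):
    return preprocess(calm_wave)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
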