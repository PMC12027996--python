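import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gazestate.events import GazeEventDetector
from gazestate.synth import GeneratorParams, TrialMeta, generate_trial

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def detector():
    return GazeEventDetector()


@pytest.fixture
def short_params():
    """Desk-scale trial parameters (short duration, default noise)."""
    return GeneratorParams(trial_duration=12.0)


@pytest.fixture
def noiseless_params():
    """Noise-free parameters for exact detector-recovery oracles."""
    return GeneratorParams(trial_duration=12.0, fixation_noise_sd=0.0,
                           pupil_noise_sd=0.0)


@pytest.fixture(scope="session")
def static_trial():
    """One noisy static-fixation rivalry trial with ground truth."""
    params = GeneratorParams(trial_duration=15.0)
    meta = TrialMeta("S01", "gaze_stability", "RG", 1, seed=42)
    stream, truth = generate_trial(meta, params)
    return stream, truth, params


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
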