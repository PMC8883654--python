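import numpy as np
import pytest
from hypothesis import settings

from hrvo2.pipeline import run_study
from hrvo2.synthetic_data import CohortConfig, sample_cohort, simulate_study

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noise_free_config():
    return CohortConfig(n_women=2, n_men=2, seed=42).noise_free()


@pytest.fixture(scope="session")
def noise_free_study(noise_free_config):
    """Noise-free simulated study: cohort, recordings, processed result."""
    cohort = sample_cohort(noise_free_config)
    recordings = simulate_study(cohort, noise_free_config)
    result = run_study(recordings)
    return cohort, recordings, result


@pytest.fixture(scope="session")
def noisy_small_study():
    """Default-noise study with a small cohort, processed end to end."""
    cfg = CohortConfig(n_women=3, n_men=3, seed=7)
    cohort = sample_cohort(cfg)
    recordings = simulate_study(cohort, cfg)
    result = run_study(recordings)
    return cohort, recordings, result


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
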