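import numpy as np
import pytest

from hairdyn import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small 3-element cohort with a strong case effect, reused across tests."""
    cfg = CohortConfig(n_subjects=16, case_fraction=0.5, n_elements=3,
                       effect_size=0.8, seed=21)
    records, profiles = generate_cohort(cfg)
    return cfg, records, profiles


@pytest.fixture(scope="session")
def sine_series():
    """Noiseless sine, period 40 samples, length 660."""
    t = np.arange(660)
    return np.sin(2 * np.pi * t / 40)


@pytest.fixture(scope="session")
def noise_series():
    return np.random.default_rng(42).uniform(size=660)
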