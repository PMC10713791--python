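import numpy as np
import pytest

from msstm.synthetic_data import (
    GeneratorConfig,
    make_prototypes,
    simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def prototypes5():
    """Five orthogonal zero-mean unit-norm 28-channel topographies."""
    return make_prototypes(5, 28, seed=42)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic dataset shared by read-only tests."""
    cfg = GeneratorConfig(
        n_subjects=3, n_trials=2, trial_duration=4.0, snr=10.0, seed=7
    )
    return simulate_dataset(cfg)
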