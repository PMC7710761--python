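"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from mlcsp.core import ParadigmSpec
from mlcsp.pipeline import preprocessed_session
from mlcsp.simulate import SimulationConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """One-run session with 10 trials per class: fast but fully structured."""
    params = dict(
        paradigm=ParadigmSpec(trials_per_class=10, runs=1),
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_session():
    """Preprocessed 80-trial session at the default noise level."""
    return preprocessed_session(small_config(seed=3))


@pytest.fixture(scope="session")
def clean_session():
    """High-SNR preprocessed 80-trial session (nearly separable classes)."""
    return preprocessed_session(small_config(seed=4, noise_amplitude=0.5))
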