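"""Shared fixtures: small synthetic configurations reused across test modules.

Session-scoped fixtures hold the expensive simulations (cortical model,
noise-free session) so the suite stays fast; tests must not mutate them.
"""

import numpy as np
import pytest

from lamconn.contrast import pair_series
from lamconn.synth import (
    MotionSpec,
    SyntheticConfig,
    make_cortical_model,
    simulate_session,
)


def clean_config(**overrides) -> SyntheticConfig:
    """Noise-free, drift-free, motion-free configuration."""
    base = dict(
        noise_sd=0.0,
        drift_amp=0.0,
        n_pairs=40,
        motion=MotionSpec(rw_scale=0.0, glitch_fraction=0.0),
        seed=3,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def cfg_clean():
    return clean_config()


@pytest.fixture(scope="session")
def model_clean(cfg_clean):
    return make_cortical_model(cfg_clean)


@pytest.fixture(scope="session")
def session_clean(cfg_clean, model_clean):
    """(series, motion, truth) of a noise-free session."""
    return simulate_session(cfg_clean, model_clean)


@pytest.fixture(scope="session")
def paired_clean(session_clean):
    series, _, _ = session_clean
    return pair_series(series)


@pytest.fixture(scope="session")
def cfg_noisy():
    return SyntheticConfig(seed=5)


@pytest.fixture(scope="session")
def model_noisy(cfg_noisy):
    return make_cortical_model(cfg_noisy)


@pytest.fixture(scope="session")
def session_noisy(cfg_noisy, model_noisy):
    return simulate_session(cfg_noisy, model_noisy)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
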