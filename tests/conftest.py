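import numpy as np
import pytest

from bethedge import (
    ModelConfig,
    integrate_fractions,
    make_dormancy_model,
    make_symmetric_model,
    sample_environment,
)


@pytest.fixture
def symmetric_config():
    """Slow-environment responsive symmetric preset (mu - rho = 3)."""
    return make_symmetric_model(mu=4.0, rho=1.0, ka=0.1, kb=1.2, lam=0.1)


@pytest.fixture
def dormancy_config():
    return make_dormancy_model(mu1=2.0, mu2=1.0, k=0.01, lam21=0.5, Px1=0.5)


@pytest.fixture
def uniform_growth_config():
    """Single-individual limit: no selection, responsive switching."""
    return ModelConfig(
        growth=np.zeros((2, 2)),
        switching=np.array([[0.1, 1.2], [1.2, 0.1]]),
        env_rates=(0.1, 0.1),
    )


@pytest.fixture
def short_run(symmetric_config):
    """A small aligned (environment, fraction) trajectory pair."""
    env = sample_environment(symmetric_config.env_rates, 300, seed=11)
    frac = integrate_fractions(env, symmetric_config, output_resolution=20)
    return env, frac
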