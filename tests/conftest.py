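import numpy as np
import pytest

from alchemforge.synthetic_fixtures import (
    FixtureEmbedder,
    make_surrogate_ensemble,
    make_toy_molecules,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def water():
    return make_toy_molecules("water")[0]


@pytest.fixture
def ethanol():
    return make_toy_molecules("ethanol")[0]


@pytest.fixture
def quiet_ensemble():
    """Surrogate ensemble with zero disagreement (rho == 0 everywhere)."""
    return make_surrogate_ensemble(k=4, amplitude=0.0, seed=1)


@pytest.fixture
def noisy_ensemble():
    """Surrogate ensemble with stretch-localized disagreement."""
    return make_surrogate_ensemble(k=4, amplitude=0.05, localization="stretch", seed=2)


@pytest.fixture
def fixture_embedder():
    return FixtureEmbedder()
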