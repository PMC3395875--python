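import numpy as np
import pytest

from phosvote import EnsembleSpec, default_scenario, simulate_ensemble


@pytest.fixture(scope="session")
def scenario():
    """The fixed 15-predictor benchmark scenario (2000 balanced sites)."""
    return default_scenario()


@pytest.fixture(scope="session")
def small_ensemble():
    """A quick 3-predictor ensemble: one strong, one weak, one near-chance."""
    spec = EnsembleSpec(
        n_sites=400, positive_fraction=0.5,
        sn=(0.9, 0.7, 0.55), sp=(0.9, 0.7, 0.5), rho=0.0, seed=7,
    )
    return simulate_ensemble(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
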