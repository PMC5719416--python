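import numpy as np
import pytest

from odorref import scenarios
from odorref.simulate import NoiseModel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170)


@pytest.fixture(scope="session")
def shared_experiment():
    """7-animal cohort, 3 reference + 2 test odorants sharing receptors,
    5 concentrations, default noise."""
    return scenarios.five_odorant_experiment(seed=1)


@pytest.fixture(scope="session")
def disjoint_experiment():
    """Same design but test odorants drive only receptors untouched by
    any reference odorant (the stated failure mode)."""
    return scenarios.five_odorant_experiment(seed=1, variant="disjoint")


@pytest.fixture(scope="session")
def mixture_experiment():
    """10-animal, 4-test-class mixture panel."""
    return scenarios.mixture_panel_experiment(seed=1)


@pytest.fixture(scope="session")
def tiny_noiseless_experiment():
    """3 animals, zero noise, small grid: exact mixing-invariance regime."""
    return scenarios.five_odorant_experiment(
        seed=5, n_animals=3, n_train=2, shape=(12, 10),
        noise=NoiseModel(additive_sd=0.0))
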