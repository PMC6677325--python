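import numpy as np
import pytest

from dsdrift.evolution import EvoParams, equilibrate_and_sample_ancestors
from dsdrift.gpmap import ModelParams


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def evolved_genome(params):
    """A well-adapted genome from a strongly selected equilibration run."""
    evo = EvoParams(two_N_kappa=100.0, rng_seed=99)
    [g] = equilibrate_and_sample_ancestors(
        params, evo, n_burn=4000, n_gap=50, n_samples=1,
        rng=np.random.default_rng(99))
    return g
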