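import numpy as np
import pytest

from metaprior import SimConfig, simulate_annotations, simulate_collection


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_studies=4, n_genes=200, n_proteins=60,
                     n_metabolites=40, n_neg=15, n_pos=15, seed=11)


@pytest.fixture(scope="session")
def small_collection(small_config):
    return simulate_collection(small_config, "transcript")


@pytest.fixture(scope="session")
def small_annotations(small_config):
    return simulate_annotations(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
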