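import numpy as np
import pytest

from celladapt import synthdata as sd


@pytest.fixture(scope="session")
def colo858_vem_params():
    return sd.get_preset("fate", "colo858_vem")


@pytest.fixture(scope="session")
def colo858_dmso_params():
    return sd.get_preset("fate", "colo858_dmso")


@pytest.fixture(scope="session")
def mmacsf_vem_params():
    return sd.get_preset("fate", "mmacsf_vem")


@pytest.fixture(scope="session")
def colo858_cohort(colo858_vem_params):
    """The reference drug-treated cohort (n=300, seed=1) used across tests."""
    return sd.simulate_fate_cohort(colo858_vem_params, 300, seed=1)


@pytest.fixture(scope="session")
def dmso_cohort(colo858_dmso_params):
    return sd.simulate_untreated_cohort(colo858_dmso_params, 200, seed=2)


def noiseless(params):
    return params.replace(noise_sd=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
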