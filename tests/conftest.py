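import numpy as np
import pytest

from thermotarget import SimConfig, make_ground_truth, normalize, summarize_to_protein
from thermotarget.synthetic import simulate_pal, simulate_pisa, simulate_tpp


@pytest.fixture
def small_config():
    return SimConfig(seed=123, n_proteins=40, n_targets=1)


@pytest.fixture
def small_truth(small_config):
    return make_ground_truth(small_config)


@pytest.fixture
def noiseless_config():
    return SimConfig(
        seed=123, n_proteins=20, n_targets=1, reporter_noise_cv=0.0, decoy_fraction=0.0
    )


def protein_table(simulate, config, truth, mode):
    """Simulate one arm and summarize/normalize without PSM filtering."""
    table, design = simulate(config, truth)
    pq = normalize(summarize_to_protein(table), design, mode=mode)
    return pq, design


@pytest.fixture
def tpp_protein_table(small_config, small_truth):
    return protein_table(simulate_tpp, small_config, small_truth, "tpp")


@pytest.fixture
def pisa_protein_table(small_config, small_truth):
    return protein_table(simulate_pisa, small_config, small_truth, "global")


@pytest.fixture
def pal_protein_table(small_config, small_truth):
    return protein_table(simulate_pal, small_config, small_truth, "global")


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
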