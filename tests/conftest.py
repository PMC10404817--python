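import pytest

from brainreg.simulate import SimulationConfig, simulate_all


SMALL_KW = dict(n_genes=400, n_true_psbeg=8, samples_per_tissue=6,
                n_peaks=60, n_recnes=12, n_loops=15, seed=11)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(**SMALL_KW)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One simulated bundle shared by read-only tests."""
    return simulate_all(small_config)
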