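import pytest

from obpdiv.simulate import SimulationConfig, simulate_haplotypes, write_dataset


@pytest.fixture(scope="session")
def dataset():
    """One synthetic SB/Sb/outgroup dataset shared across the suite."""
    return simulate_haplotypes(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, dataset):
    """The same dataset written to disk in pipeline formats."""
    d = tmp_path_factory.mktemp("ds")
    write_dataset(dataset, d)
    return d
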