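import pytest

from exonsplice import ExonArrayAnalysis, simulate_dataset


@pytest.fixture(scope="session")
def dataset200():
    """Simulated 200-gene study with injected events and one outlier."""
    return simulate_dataset(n_genes=200, seed=1)


@pytest.fixture(scope="session")
def results200(dataset200):
    study, _truth = dataset200
    return ExonArrayAnalysis(study).fit()


@pytest.fixture(scope="session")
def truth200(dataset200):
    return dataset200[1]
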