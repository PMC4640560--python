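import pytest

from mirovary import SimulationParams, generate_catalog, simulate_library


@pytest.fixture(scope="session")
def small_params():
    """A small, fast study-shaped simulation: 40 genes, 2e5 reads."""
    return SimulationParams(n_mirnas=40, depth=200_000, n_enriched=3, seed=11)


@pytest.fixture(scope="session")
def small_catalog(small_params):
    return generate_catalog(small_params)


@pytest.fixture(scope="session")
def tissue_library(small_catalog, small_params):
    return simulate_library(small_catalog, small_params, "tissue1", tissue=True)
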