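import pytest
from hypothesis import settings

from cerna_scope.synthetic import SimulationConfig, simulate_all

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down planted study used across the unit tests."""
    return SimulationConfig(
        n_genes=400,
        n_lncrnas=120,
        n_mirnas=60,
        n_planted_triplets=6,
        n_negative_correlated=2,
        n_negative_shared=2,
        n_drugs=10,
        n_terms=20,
        genes_per_term=8,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_all(small_config)
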