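import pytest

from efos import (
    SimulationConfig,
    load_reference_matrix,
    renormalize_rows,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def reference_matrix():
    """Packaged averaged matrix, as printed (rows sum to ~1 +/- 0.001)."""
    return load_reference_matrix()


@pytest.fixture(scope="session")
def reference_renormalized(reference_matrix):
    return renormalize_rows(reference_matrix)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated dataset shared across tests (seeded)."""
    return simulate_dataset(SimulationConfig(n_matches=12, rallies_per_match=60, seed=11))
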