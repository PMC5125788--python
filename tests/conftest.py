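import pytest

from barcodeid import (
    DivergenceSpec, TaxonomySpec, simulate_library, simulate_queries,
)

DEFAULT_DIVERGENCE = DivergenceSpec(seed=42)
DEFAULT_TAXONOMY = TaxonomySpec()


@pytest.fixture(scope="session")
def library():
    """Default simulated reference library (5x2x3x4, 657 bp, seed 42)."""
    records, truth = simulate_library(DEFAULT_TAXONOMY, DEFAULT_DIVERGENCE)
    return records, truth


@pytest.fixture(scope="session")
def queries(library):
    """Default mixed query set (30 conspecific / 15 novel-species /
    15 novel-genus, seed 42)."""
    records, _ = library
    return simulate_queries(records, seed=42, divergence=DEFAULT_DIVERGENCE)


@pytest.fixture(scope="session")
def small_library():
    """Tiny library for fast end-to-end tests: 2x1x2x3, 300 bp."""
    taxonomy = TaxonomySpec(n_families=2, genera_per_family=1,
                            species_per_genus=2, specimens_per_species=3)
    divergence = DivergenceSpec(seq_length=300, seed=7)
    records, truth = simulate_library(taxonomy, divergence)
    return records, truth, divergence
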