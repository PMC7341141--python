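import pytest

from qtgrank.model import ModelConfig
from qtgrank.simulate import FixtureSpec, generate_species


@pytest.fixture(scope="session")
def small_species():
    """A small synthetic species with the default planted effects."""
    return generate_species(
        FixtureSpec(n_genes=400, n_causal=50, n_qtls=4, qtl_size_range=(20, 80), seed=42)
    )


@pytest.fixture(scope="session")
def fast_config():
    """Forest/ensemble settings small enough for unit tests."""
    return ModelConfig(n_trees=30, n_ensemble_iterations=5, seed=7)
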