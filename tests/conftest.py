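import pytest

import funlink as fl


@pytest.fixture(scope="session")
def default_fixture():
    """Default-condition compendium with planted modules."""
    comp, truth = fl.generate_compendium(fl.FixtureConfig(seed=1))
    return comp, truth


@pytest.fixture(scope="session")
def dense_fixture():
    """Few large modules: a dense planted network for GSLA / PR tests."""
    cfg = fl.FixtureConfig(
        n_genes=150,
        n_modules=4,
        module_size_range=(12, 16),
        heldout_fraction=0.0,
        seed=11,
    )
    comp, truth = fl.generate_compendium(cfg)
    return comp, truth


@pytest.fixture(scope="session")
def small_dag():
    return fl.balanced_tree_ontology(depth=3, branching=2)
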