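import numpy as np
import pytest

from gutrhythm.config import Config
from gutrhythm.datamodel import FeatureTable, RootedTree, TaxonomyMap
from gutrhythm.simulate import generate_cohort


@pytest.fixture(scope="session")
def worked_tree() -> RootedTree:
    """((A:1,B:1):1,(C:1,D:1):1); — the 4-tip worked example."""
    return RootedTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def star_tree() -> RootedTree:
    return RootedTree.from_newick("(A:1,B:1,C:1,D:1);")


@pytest.fixture(scope="session")
def small_bundle():
    """A small deterministic synthetic cohort shared across tests."""
    cfg = Config()
    cfg.synthetic.n_infants = 5
    return generate_cohort(cfg.synthetic, seed=7)


@pytest.fixture
def tiny_table() -> FeatureTable:
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 50, size=(6, 8))
    return FeatureTable(
        [f"s{i}" for i in range(6)], [f"f{j}" for j in range(8)], counts
    )


@pytest.fixture
def flat_taxonomy() -> TaxonomyMap:
    return TaxonomyMap(
        {
            f"f{j}": ["Bacteria", "Firmicutes", "", "", "FamX", f"Genus{j % 3}"]
            for j in range(8)
        }
    )
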