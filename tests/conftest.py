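import numpy as np
import pytest

import phylolandscape as pl


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def abc_tree():
    """The worked 3-tip example tree with branch lengths."""
    return pl.trees_from_string("((A:1,B:1):1,C:2);")[0]


@pytest.fixture(scope="session")
def benchmark_islands():
    """The standard 4-island benchmark: 4 x 50 trees, 20 tips, 2 NNI moves."""
    return pl.make_islands(pl.IslandSpec(seed=7))


@pytest.fixture(scope="session")
def random_collection():
    """30 unrelated random 10-tip trees with branch lengths."""
    rng = np.random.default_rng(42)
    import dendropy

    tns = dendropy.TaxonNamespace()
    trees = [pl.random_tree(10, rng, taxon_namespace=tns) for _ in range(30)]
    return pl.TreeCollection(trees)
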