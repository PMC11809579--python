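import numpy as np
import pytest

from phyloval import simulate
from phyloval.simulate import CoalescentParams


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def coalescent_tree(rng):
    """One validated 5-tip Kingman tree."""
    return simulate.simulate_coalescent(CoalescentParams(5), rng).validate()


@pytest.fixture
def random_trees(rng):
    """A mixed bag of simulated ultrametric trees, sizes 3..20."""
    trees = []
    for s in range(3, 21):
        trees.append(simulate.simulate_coalescent(CoalescentParams(s), rng))
        trees.append(simulate.simulate_yule_ntips(0.8, s, rng))
    return trees
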