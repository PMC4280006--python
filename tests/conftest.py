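import numpy as np
import pytest

import gmycdelim as g


@pytest.fixture
def three_tip_tree():
    return g.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip_tree():
    """Two shallow cherries on a deep split; the canonical threshold fixture."""
    return g.read_newick("((A:0.1,B:0.1):1.9,(C:0.2,D:0.2):1.8);")


@pytest.fixture
def balanced_entity_tree():
    return g.read_newick("((e1:1,e2:1):2,(e3:2,e4:2):1);")


def random_ultrametric_tree(rng: np.random.Generator, n_tips: int) -> g.UltrametricTree:
    """Random coalescent-shaped ultrametric tree for property tests."""
    from gmycdelim.synthetic_data import _coalescent_subtree, _coalescent_times
    from gmycdelim.treeio import UltrametricTree

    times = _coalescent_times(n_tips, 1.0, np.inf, rng)
    root = _coalescent_subtree("T", n_tips, times, rng)

    def fix(node):
        for c in node.children:
            c.length = node.age - c.age
            fix(c)

    fix(root)
    return UltrametricTree(root)
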