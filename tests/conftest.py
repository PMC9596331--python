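import numpy as np
import pytest

import telopace as tp


@pytest.fixture(scope="session")
def three_tip_tree():
    return tp.parse_newick_trees("((A:1,B:1):1,C:2);")[0]


@pytest.fixture(scope="session")
def yule20():
    return tp.simulate_yule_tree(20, seed=20)


@pytest.fixture(scope="session")
def birdlike():
    """One fixed synthetic 30-species dataset: (traits, tree, truth)."""
    return tp.generate_birdlike_dataset(seed=11)


@pytest.fixture(scope="session")
def small_chain():
    """Short but usable MCMC settings for structural (non-inferential) tests."""
    return {"n_iter": 1_200, "burn_in": 200, "thin": 2}


def brute_force_mrca_depths(tree, order):
    """Independent A-matrix oracle: explicit root-to-tip path enumeration.

    For every tip pair, walks both root-to-tip paths and sums the branch
    lengths of the shared prefix (the path to the MRCA), then rescales by
    the maximum tip depth. Deliberately naive.
    """
    paths = {}
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = list(reversed(path))

    n = len(order)
    mat = np.zeros((n, n))
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            shared = 0.0
            for na, nb in zip(paths[a], paths[b]):
                if na is not nb:
                    break
                shared += float(na.edge.length or 0.0)
            mat[i, j] = shared
    return mat / mat.diagonal().max()
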