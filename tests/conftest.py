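import numpy as np
import pytest

from scclonesim.tree import CellAssignment, ClonalTree, TreeNode


def make_two_clone_tree(lengths=(0.5, 1.5), intervals=(0.5,), muts=({0}, {1})):
    """Hand-built root with two leaf clones; explicit control of everything."""
    split = intervals[0]
    nodes = {
        0: TreeNode(id=0, interval=(0.0, 1.0), children=(1, 2)),
        1: TreeNode(id=1, parent=0, interval=(0.0, split), branch_length=lengths[0], mutation_ids=set(muts[0])),
        2: TreeNode(id=2, parent=0, interval=(split, 1.0), branch_length=lengths[1], mutation_ids=set(muts[1])),
    }
    return ClonalTree(nodes=nodes, root_id=0, n_leaves=2, beta_split=0.5)


def make_chain_tree():
    """Root -> (clone A, internal) ; internal -> (clone B1, clone B2).

    Mutation 0 sits on the edge under the root leading to the internal
    node, so both deeper clones inherit it.
    """
    nodes = {
        0: TreeNode(id=0, interval=(0.0, 1.0), children=(1, 2)),
        1: TreeNode(id=1, parent=0, interval=(0.0, 0.5), branch_length=1.0, mutation_ids={1}),
        2: TreeNode(id=2, parent=0, interval=(0.5, 1.0), branch_length=1.0, mutation_ids={0}, children=(3, 4)),
        3: TreeNode(id=3, parent=2, interval=(0.5, 0.75), branch_length=1.0, mutation_ids={2}),
        4: TreeNode(id=4, parent=2, interval=(0.75, 1.0), branch_length=1.0, mutation_ids={3}),
    }
    return ClonalTree(nodes=nodes, root_id=0, n_leaves=3, beta_split=0.5)


@pytest.fixture
def two_clone_tree():
    return make_two_clone_tree()


@pytest.fixture
def chain_tree():
    return make_chain_tree()


@pytest.fixture
def balanced_assignment():
    return CellAssignment(
        cell_to_leaf=np.array([0, 0, 1, 1]), leaf_sizes=np.array([2, 2])
    )
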