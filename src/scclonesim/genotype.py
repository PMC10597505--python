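"""True genotype matrix G and its perfect-phylogeny structure.

G is the N x M binary cells-by-mutations matrix: G[i, j] = 1 iff mutation j
lies on the root-to-leaf path of cell i's clone.  Because mutations are
placed on tree edges and inherited without loss (infinite-sites / perfect
phylogeny), the mutation columns form a laminar family: the cell sets
carrying any two mutations are either nested or disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import CellAssignment, ClonalTree

__all__ = ["GenotypeMatrix", "build_G", "clone_consensus", "is_laminar"]


@dataclass
class GenotypeMatrix:
    values: np.ndarray  # N x M, int8 in {0, 1}
    cell_ids: np.ndarray
    mutation_ids: np.ndarray
    clone_labels: np.ndarray  # length-N ground-truth clustering

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_mutations(self) -> int:
        return self.values.shape[1]


def build_G(tree: ClonalTree, assignment: CellAssignment) -> GenotypeMatrix:
    """Assemble G from the tree's edge mutations and the cell assignment."""
    leaf_ids = tree.leaf_ids
    K = len(leaf_ids)
    M = sum(len(tree.nodes[nid].mutation_ids) for nid in tree.edge_node_ids)
    if M == 0:
        raise ValueError("no mutations assigned to the tree; call assign_mutations first")
    seen: set[int] = set()
    for nid in tree.edge_node_ids:
        seen |= tree.nodes[nid].mutation_ids
    if seen != set(range(M)):
        raise ValueError("mutation ids on edges are not exactly 0..M-1")

    clone_rows = np.zeros((K, M), dtype=np.int8)
    for k, leaf in enumerate(leaf_ids):
        clone_rows[k, sorted(tree.path_mutations(leaf))] = 1

    labels = assignment.cell_to_leaf
    values = clone_rows[labels]
    return GenotypeMatrix(
        values=values,
        cell_ids=np.arange(labels.size),
        mutation_ids=np.arange(M),
        clone_labels=labels.copy(),
    )


def clone_consensus(G: GenotypeMatrix, clone: int) -> np.ndarray:
    """The shared genotype row of a clone; errors if rows disagree."""
    rows = G.values[G.clone_labels == clone]
    if rows.size == 0:
        raise ValueError(f"clone {clone} has no cells")
    if (rows != rows[0]).any():
        raise ValueError(f"clone {clone} has heterogeneous genotype rows")
    return rows[0].copy()


def is_laminar(values: np.ndarray) -> bool:
    """Pairwise laminar-family (perfect phylogeny) check on the columns.

    For every pair of mutation columns the supporting cell sets must be
    nested or disjoint; equivalently the three-gamete condition restricted
    to binary data with no back mutation.
    """
    A = values.astype(bool)
    both = A.T.astype(np.int64) @ A.astype(np.int64)  # |i ∩ j|
    sizes = A.sum(axis=0).astype(np.int64)
    inter = both
    disjoint = inter == 0
    nested = (inter == sizes[:, None]) | (inter == sizes[None, :])
    return bool((disjoint | nested).all())
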