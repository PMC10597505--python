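"""Clonal tree generation by reverse Beta-splitting.

A tumor's subclonal structure is modeled as a rooted binary tree whose
leaves are subclones (clusters of cells with identical genotypes).  Every
node owns a half-open sub-interval of [0, 1); the two children of a node
partition its interval, so leaf interval lengths always sum to 1.  The
interval length of a leaf later determines the expected size of the
corresponding cell cluster, which makes the split-ratio distribution a
direct dial for cluster-size contrast.

Growth rule ("reverse splitting"): starting from the root, a current leaf
is chosen to split with probability proportional to *one minus* its
interval length, so small clones keep splitting while large clones are
retained — increasing the contrast between cluster sizes.  The fraction of
the parent interval given to the left child is drawn from Beta(0.5, beta);
smaller ``beta`` skews splits and therefore cluster sizes.  Once the
topology has the requested number of leaves, each edge receives an
i.i.d. Exponential(rate=1) branch length; mutations are then distributed
over edges in proportion to branch length and cells over leaves in
proportion to interval length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TreeNode",
    "ClonalTree",
    "CellAssignment",
    "grow_tree",
    "assign_mutations",
    "assign_cells",
    "cluster_size_sd",
    "write_newick",
    "to_newick",
]

#: Default number of multinomial redraws before a degenerate draw is repaired.
MAX_REDRAWS = 1000

ALPHA = 0.5  # first shape parameter of the split-ratio Beta; fixed.


@dataclass
class TreeNode:
    id: int
    parent: int | None = None
    children: tuple[int, int] | None = None
    interval: tuple[float, float] = (0.0, 1.0)
    branch_length: float = 0.0
    mutation_ids: set[int] = field(default_factory=set)

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def interval_length(self) -> float:
        return self.interval[1] - self.interval[0]


@dataclass
class ClonalTree:
    """Binary clone tree with per-node intervals and branch lengths.

    ``leaf_ids`` orders the leaves; position k in that list is clone k.
    """

    nodes: dict[int, TreeNode]
    root_id: int
    n_leaves: int
    beta_split: float
    rng_seed: int | None = None

    @property
    def leaf_ids(self) -> list[int]:
        return sorted(nid for nid, n in self.nodes.items() if n.is_leaf)

    @property
    def edge_node_ids(self) -> list[int]:
        """Non-root node ids; each owns the edge to its parent."""
        return sorted(nid for nid in self.nodes if nid != self.root_id)

    def leaf_interval_lengths(self) -> np.ndarray:
        return np.array([self.nodes[i].interval_length for i in self.leaf_ids])

    def root_path(self, node_id: int) -> list[int]:
        """Node ids from the root (exclusive) down to ``node_id`` (inclusive)."""
        path = []
        nid: int | None = node_id
        while nid is not None and nid != self.root_id:
            path.append(nid)
            nid = self.nodes[nid].parent
        return path[::-1]

    def path_mutations(self, leaf_id: int) -> set[int]:
        muts: set[int] = set()
        for nid in self.root_path(leaf_id):
            muts |= self.nodes[nid].mutation_ids
        return muts

    def validate(self, atol: float = 1e-9) -> None:
        root = self.nodes[self.root_id]
        if root.parent is not None or root.mutation_ids:
            raise ValueError("root must be parentless and mutation-free")
        for n in self.nodes.values():
            if n.children is not None:
                a, b = (self.nodes[c] for c in n.children)
                if not (
                    abs(a.interval[0] - n.interval[0]) <= atol
                    and abs(a.interval[1] - b.interval[0]) <= atol
                    and abs(b.interval[1] - n.interval[1]) <= atol
                ):
                    raise ValueError(f"children of node {n.id} do not partition its interval")
        if abs(self.leaf_interval_lengths().sum() - 1.0) > atol:
            raise ValueError("leaf interval lengths do not sum to 1")
        if len(self.leaf_ids) != self.n_leaves:
            raise ValueError("leaf count does not match n_leaves")


@dataclass
class CellAssignment:
    """Mapping of cells to clone indices (0..K-1), clone-blocked order."""

    cell_to_leaf: np.ndarray  # length-N vector of clone indices
    leaf_sizes: np.ndarray  # length-K
    permutation: np.ndarray | None = None  # applied shuffle, if any

    @property
    def n_cells(self) -> int:
        return int(self.cell_to_leaf.size)

    @property
    def n_clones(self) -> int:
        return int(self.leaf_sizes.size)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def grow_tree(K: int, beta_split: float, seed=None) -> ClonalTree:
    """Grow a clone tree with ``K`` leaves by reverse Beta-splitting.

    At every step a current leaf is selected with probability proportional
    to (1 - interval length), normalized over current leaves; the lone root
    is split unconditionally.  The selected leaf receives two children; the
    left child gets a fraction p ~ Beta(0.5, beta_split) of the parent
    interval.  After the topology is complete, every edge length is drawn
    i.i.d. Exponential(rate=1).
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    if not beta_split > 0:
        raise ValueError(f"beta_split must be > 0, got {beta_split}")
    rng = _as_rng(seed)

    nodes = {0: TreeNode(id=0, interval=(0.0, 1.0))}
    next_id = 1
    leaves = [0]
    while len(leaves) < K:
        weights = np.array([1.0 - nodes[i].interval_length for i in leaves])
        total = weights.sum()
        if total <= 0.0:  # only the root exists: forced split
            idx = 0
        else:
            idx = rng.choice(len(leaves), p=weights / total)
        parent = nodes[leaves[idx]]
        p = rng.beta(ALPHA, beta_split)
        s, e = parent.interval
        mid = s + p * (e - s)
        left = TreeNode(id=next_id, parent=parent.id, interval=(s, mid))
        right = TreeNode(id=next_id + 1, parent=parent.id, interval=(mid, e))
        nodes[left.id] = left
        nodes[right.id] = right
        parent.children = (left.id, right.id)
        next_id += 2
        leaves[idx] = left.id
        leaves.append(right.id)

    for nid, node in nodes.items():
        if nid != 0:
            node.branch_length = float(rng.exponential(1.0))

    tree = ClonalTree(
        nodes=nodes,
        root_id=0,
        n_leaves=K,
        beta_split=beta_split,
        rng_seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
    tree.validate()
    return tree


def _multinomial_min_one(
    n: int,
    probs: np.ndarray,
    rng: np.random.Generator,
    max_redraws: int = MAX_REDRAWS,
) -> np.ndarray:
    """Multinomial draw conditioned on every category being non-empty.

    Rejection-samples up to ``max_redraws`` times.  Heavy-tailed interval or
    branch-length distributions can make the non-empty event vanishingly
    rare, so on exhaustion the last draw is repaired: one unit is moved from
    the currently largest category into each empty one.  This keeps the
    total exact and perturbs at most K-1 units.
    """
    k = probs.size
    if n < k:
        raise ValueError(f"cannot fill {k} categories with only {n} items")
    counts = rng.multinomial(n, probs)
    for _ in range(max_redraws):
        if (counts > 0).all():
            return counts
        counts = rng.multinomial(n, probs)
    while (counts == 0).any():
        empty = np.flatnonzero(counts == 0)
        donor = int(np.argmax(counts))
        take = min(len(empty), counts[donor] - 1)
        if take <= 0:
            raise RuntimeError("cannot repair draw: no donor category")
        counts[empty[:take]] = 1
        counts[donor] -= take
    return counts


def assign_mutations(tree: ClonalTree, M: int, seed=None) -> ClonalTree:
    """Distribute mutation ids 0..M-1 over edges, multinomially by length.

    Every edge is required to end up with at least one mutation so that
    every clone has a distinct genotype; see ``_multinomial_min_one``.
    Mutates ``tree`` in place and returns it.
    """
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    rng = _as_rng(seed)
    edge_ids = tree.edge_node_ids
    lengths = np.array([tree.nodes[i].branch_length for i in edge_ids], dtype=float)
    if lengths.sum() <= 0:
        raise ValueError("tree has no positive edge lengths; call grow_tree first")
    if M < len(edge_ids):
        raise ValueError(
            f"M={M} mutations cannot cover {len(edge_ids)} edges with one each"
        )
    counts = _multinomial_min_one(M, lengths / lengths.sum(), rng)
    # deal ids edge by edge, randomized so ids carry no positional signal
    ids = rng.permutation(M)
    start = 0
    for eid, c in zip(edge_ids, counts):
        tree.nodes[eid].mutation_ids = set(int(i) for i in ids[start : start + c])
        start += c
    return tree


def assign_cells(tree: ClonalTree, N: int, seed=None, shuffle: bool = False) -> CellAssignment:
    """Assign ``N`` cells to leaves multinomially by interval length.

    Every clone receives at least one cell.  Cells are clone-blocked (all
    cells of clone 0 first, then clone 1, ...); with ``shuffle=True`` the
    order is permuted and the permutation recorded.
    """
    K = tree.n_leaves
    if N < K:
        raise ValueError(f"N={N} must be >= K={K}")
    rng = _as_rng(seed)
    lengths = tree.leaf_interval_lengths()
    sizes = _multinomial_min_one(N, lengths / lengths.sum(), rng)
    cell_to_leaf = np.repeat(np.arange(K), sizes)
    perm = None
    if shuffle:
        perm = rng.permutation(N)
        cell_to_leaf = cell_to_leaf[perm]
    return CellAssignment(cell_to_leaf=cell_to_leaf, leaf_sizes=sizes, permutation=perm)


def cluster_size_sd(assignment: CellAssignment) -> float:
    """Population standard deviation (divisor K) of the K cluster sizes."""
    if assignment.n_clones < 2:
        raise ValueError("need at least 2 clusters")
    return float(np.std(assignment.leaf_sizes))


def to_newick(tree: ClonalTree) -> str:
    """Newick string with leaves labelled ``clone<k>`` and branch lengths."""
    clone_of = {leaf: k for k, leaf in enumerate(tree.leaf_ids)}

    def render(nid: int) -> str:
        node = tree.nodes[nid]
        if node.is_leaf:
            return f"clone{clone_of[nid]}:{float(node.branch_length)}"
        a, b = node.children
        return f"({render(a)},{render(b)}):{float(node.branch_length)}"

    return render(tree.root_id) + ";"


def write_newick(tree: ClonalTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
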