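"""Clonal-tree growth, mutation/cell placement, and serialization."""

import numpy as np
import pytest

import scclonesim as s
from scclonesim.tree import _multinomial_min_one

from conftest import make_two_clone_tree


class TestGrowTree:
    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            s.grow_tree(1, 0.2)
        with pytest.raises(ValueError):
            s.grow_tree(4, 0.0)

    def test_single_forced_split_partitions_unit_interval(self):
        tree = s.grow_tree(2, 0.3, seed=7)
        lengths = tree.leaf_interval_lengths()
        assert lengths.size == 2
        assert lengths.sum() == pytest.approx(1.0, abs=1e-9)
        a, b = (tree.nodes[i] for i in tree.leaf_ids)
        assert a.interval[0] == 0.0 and b.interval[1] == 1.0
        assert a.interval[1] == b.interval[0]

    @pytest.mark.parametrize("K,beta", [(2, 0.5), (8, 0.2), (16, 0.05), (32, 1.5)])
    def test_leaf_lengths_sum_to_one_and_leaf_count(self, K, beta):
        tree = s.grow_tree(K, beta, seed=11)
        assert len(tree.leaf_ids) == K
        assert tree.leaf_interval_lengths().sum() == pytest.approx(1.0, abs=1e-9)
        tree.validate()

    def test_reverse_selection_probabilities_hand_oracle(self):
        # interval lengths (0.5, 0.3, 0.2) -> weights (0.5, 0.7, 0.8),
        # normalized to (0.25, 0.35, 0.40)
        lengths = np.array([0.5, 0.3, 0.2])
        w = 1.0 - lengths
        probs = w / w.sum()
        assert probs == pytest.approx([0.25, 0.35, 0.40])
        # empirical single selections reproduce the oracle within 3 SE
        rng = np.random.default_rng(0)
        n = 10_000
        picks = rng.choice(3, size=n, p=probs)
        freq = np.bincount(picks, minlength=3) / n
        se = np.sqrt(probs * (1 - probs) / n)
        assert (np.abs(freq - probs) < 3 * se).all()

    def test_split_fraction_mean_matches_beta_mean(self):
        # Beta(0.5, 0.5) has mean 1/2; the first split's left fraction over
        # many seeded trees must match within 3 standard errors.
        n = 20_000
        rng = np.random.default_rng(123)
        fracs = np.empty(n)
        for i in range(n):
            tree = s.grow_tree(2, 0.5, rng)
            fracs[i] = tree.nodes[tree.leaf_ids[0]].interval_length
        sd = np.sqrt(0.25 * 0.25 / (0.5 + 0.5 + 1))  # Beta variance
        assert abs(fracs.mean() - 0.5) < 3 * sd / np.sqrt(n)

    def test_seeded_determinism_bit_identical(self):
        t1 = s.grow_tree(8, 0.2, seed=42)
        t2 = s.grow_tree(8, 0.2, seed=42)
        for nid in t1.nodes:
            assert t1.nodes[nid].interval == t2.nodes[nid].interval
            assert t1.nodes[nid].branch_length == t2.nodes[nid].branch_length
        s.assign_mutations(t1, 50, seed=9)
        s.assign_mutations(t2, 50, seed=9)
        for nid in t1.nodes:
            assert t1.nodes[nid].mutation_ids == t2.nodes[nid].mutation_ids
        a1 = s.assign_cells(t1, 100, seed=5)
        a2 = s.assign_cells(t2, 100, seed=5)
        assert (a1.cell_to_leaf == a2.cell_to_leaf).all()

    def test_smaller_beta_gives_larger_cluster_size_sd(self):
        # mean cluster-size dispersion must decrease monotonically in beta
        rng = np.random.default_rng(2024)
        means = []
        for beta in (0.05, 0.2, 0.5):
            sds = []
            for _ in range(200):
                tree = s.grow_tree(8, beta, rng)
                sds.append(s.cluster_size_sd(s.assign_cells(tree, 500, rng)))
            means.append(np.mean(sds))
        assert means[0] > means[1] > means[2]


class TestAssignMutations:
    def test_proportional_share_binomial_oracle(self, two_clone_tree):
        tree = make_two_clone_tree(lengths=(1.0, 3.0))
        M = 40_000
        s.assign_mutations(tree, M, seed=3)
        share = len(tree.nodes[1].mutation_ids) / M
        se = np.sqrt(0.25 * 0.75 / M)
        assert abs(share - 0.25) < 3 * se

    def test_nonzero_constraint_forces_one_each(self):
        tree = make_two_clone_tree(lengths=(1.0, 3.0))
        s.assign_mutations(tree, 2, seed=0)
        assert len(tree.nodes[1].mutation_ids) == 1
        assert len(tree.nodes[2].mutation_ids) == 1

    def test_mutation_conservation_and_disjointness(self):
        tree = s.grow_tree(8, 0.2, seed=1)
        s.assign_mutations(tree, 200, seed=1)
        all_ids = [m for nid in tree.edge_node_ids for m in tree.nodes[nid].mutation_ids]
        assert len(all_ids) == 200
        assert sorted(all_ids) == list(range(200))

    def test_too_few_mutations_for_edges_raises(self):
        tree = s.grow_tree(8, 0.2, seed=1)  # 14 edges
        with pytest.raises(ValueError):
            s.assign_mutations(tree, 5, seed=1)


class TestAssignCells:
    def test_conservation_and_nonempty(self):
        tree = s.grow_tree(8, 0.2, seed=4)
        a = s.assign_cells(tree, 500, seed=4)
        assert a.leaf_sizes.sum() == 500
        assert (a.leaf_sizes >= 1).all()
        assert a.cell_to_leaf.size == 500

    def test_mean_size_binomial_oracle(self):
        # leaf lengths (0.9, 0.1): mean size of the small clone ~ N*p = 50
        tree = make_two_clone_tree(intervals=(0.9,))
        rng = np.random.default_rng(8)
        reps = 1000
        sizes = np.array([s.assign_cells(tree, 500, rng).leaf_sizes[1] for _ in range(reps)])
        se = np.sqrt(500 * 0.1 * 0.9 / reps)
        assert abs(sizes.mean() - 50.0) < 3 * se

    def test_n_below_k_raises(self):
        tree = s.grow_tree(4, 0.2, seed=0)
        with pytest.raises(ValueError):
            s.assign_cells(tree, 3, seed=0)

    def test_shuffle_records_permutation(self):
        tree = s.grow_tree(4, 0.2, seed=0)
        a = s.assign_cells(tree, 50, seed=0, shuffle=True)
        assert a.permutation is not None
        blocked = np.repeat(np.arange(4), a.leaf_sizes)
        assert (blocked[a.permutation] == a.cell_to_leaf).all()

    def test_repair_keeps_all_clones_nonempty_under_extreme_skew(self):
        # interval lengths spanning many orders of magnitude defeat
        # rejection sampling; the repair path must still return K clones
        counts = _multinomial_min_one(
            100, np.array([1 - 3e-9, 1e-9, 1e-9, 1e-9]), np.random.default_rng(0), max_redraws=5
        )
        assert counts.sum() == 100
        assert (counts >= 1).all()


class TestClusterSizeSd:
    def test_equal_sizes_zero(self):
        from scclonesim.tree import CellAssignment

        a = CellAssignment(np.repeat([0, 1], 250), np.array([250, 250]))
        assert s.cluster_size_sd(a) == 0.0

    def test_hand_computed_population_sd(self):
        from scclonesim.tree import CellAssignment

        sizes = np.array([100, 200, 300, 400])
        a = CellAssignment(np.repeat(np.arange(4), sizes), sizes)
        assert s.cluster_size_sd(a) == pytest.approx(111.80339887498948, abs=1e-9)


class TestNewick:
    def test_exact_serialization_example(self):
        tree = make_two_clone_tree(lengths=(0.5, 1.5))
        assert s.to_newick(tree) == "(clone0:0.5,clone1:1.5):0.0;"

    def test_round_trip_through_dendropy(self, tmp_path):
        import dendropy

        tree = s.grow_tree(8, 0.2, seed=21)
        path = tmp_path / "t.nwk"
        s.write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        taxa = sorted(l.taxon.label for l in parsed.leaf_node_iter())
        assert taxa == [f"clone{k}" for k in range(8)]
        by_label = {l.taxon.label: l.edge.length for l in parsed.leaf_node_iter()}
        for k, leaf_id in enumerate(tree.leaf_ids):
            assert by_label[f"clone{k}"] == pytest.approx(
                tree.nodes[leaf_id].branch_length, abs=1e-9
            )
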