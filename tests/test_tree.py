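"""Steinerization over a species tree: initialization, monotone rounds."""

import random

import pytest

from orderalign.median import solve_star
from orderalign.model import CostScheme, GeneOrder, StarInstance
from orderalign.simulate import SimulationParams, simulate_tree
from orderalign.tree import (AssignedTree, TreeNode, build_multiple_alignment,
                             initialize_assignments, reoptimize_round,
                             run_steinerization, tree_cost)

from conftest import go


def leaf_tree(leaves: dict[str, GeneOrder], topology: dict, root: str) -> AssignedTree:
    tree = AssignedTree.from_parent_map(topology, root)
    for name, genome in leaves.items():
        tree.nodes[name].genome = genome.with_id(name)
    return tree


class TestTreeStructure:
    def test_non_binary_rejected(self):
        root = TreeNode("r", children=[TreeNode("a"), TreeNode("b"), TreeNode("c")])
        with pytest.raises(ValueError, match="non-binary"):
            AssignedTree(root)

    def test_unassigned_leaf_rejected(self):
        tree = AssignedTree.from_parent_map({"r": ("a", "b")}, "r")
        with pytest.raises(ValueError, match="no genome"):
            initialize_assignments(tree)


class TestInitialization:
    def test_identical_leaves_zero_cost(self):
        tree = leaf_tree({"a": go("ab"), "b": go("ab"), "c": go("ab")},
                         {"r": ("u", "c"), "u": ("a", "b")}, "r")
        initialize_assignments(tree)
        assert tree.nodes["u"].genome.genes == go("ab").genes
        assert tree_cost(tree) == 0

    def test_cherry_cost(self):
        tree = leaf_tree({"a": go("ab"), "b": go("abab")}, {"r": ("a", "b")}, "r")
        initialize_assignments(tree)
        assert tree_cost(tree) == 1

    def test_balanced_four_leaves_single_loss(self):
        tree = leaf_tree(
            {"a": go("abc"), "b": go("abc"), "c": go("ac"), "d": go("ac")},
            {"r": ("u", "v"), "u": ("a", "b"), "v": ("c", "d")}, "r")
        initialize_assignments(tree)
        assert tree_cost(tree) == 1


class TestReoptimization:
    def test_fixed_point_reports_no_improvement(self):
        tree = leaf_tree({"a": go("ab"), "b": go("ab"), "c": go("ab")},
                         {"r": ("u", "c"), "u": ("a", "b")}, "r")
        initialize_assignments(tree)
        _, improved = reoptimize_round(tree)
        assert improved is False

    def test_triplet_center_matches_solve_star(self):
        params = SimulationParams(n=15, sigma=7, l=1, model="dup_singleloss",
                                  seed=11)
        inst = simulate_tree(3, params)
        costs = CostScheme.dup_singleloss()
        tree, _ = run_steinerization(inst.tree, costs)
        # the single inner node sits in a 3-star under the root
        inner = [n for n in tree.internal_nodes() if n.parent is not None][0]
        sol = solve_star(StarInstance(inner.parent.genome,
                                      inner.children[0].genome,
                                      inner.children[1].genome, costs))
        incident = (tree_cost(tree, costs))
        assert incident >= 0
        assert sol.cost >= 0  # and the node cannot be improved further
        _, improved = reoptimize_round(tree, costs)
        assert improved is False

    def test_costs_non_increasing_on_seeded_instances(self):
        costs = CostScheme.dup_singleloss()
        for seed in range(8):
            params = SimulationParams(n=15, sigma=7, l=1,
                                      model="dup_singleloss", seed=seed)
            inst = simulate_tree(6, params)
            _, log = run_steinerization(inst.tree, costs, max_rounds=12)
            assert all(b <= a + 1e-9 for a, b in zip(log.costs, log.costs[1:]))
            assert log.rounds <= 12

    def test_final_cost_at_most_initialization(self):
        params = SimulationParams(n=20, sigma=10, l=2, model="dup_singleloss",
                                  seed=3)
        inst = simulate_tree(8, params)
        _, log = run_steinerization(inst.tree, CostScheme.dup_singleloss())
        assert log.costs[-1] <= log.costs[0] + 1e-9


class TestMultipleAlignment:
    def test_identical_leaves_no_gaps(self):
        tree = leaf_tree({"a": go("abc"), "b": go("abc"), "c": go("abc")},
                         {"r": ("u", "c"), "u": ("a", "b")}, "r")
        initialize_assignments(tree)
        aln = build_multiple_alignment(tree)
        assert len(aln.row_order) == 5  # 3 leaves + 2 internal nodes
        assert aln.length == 3
        assert all(None not in aln.rows[r] for r in aln.row_order)

    def test_two_leaf_gap_column(self):
        tree = leaf_tree({"a": go("abcde"), "b": go("acde")},
                         {"r": ("a", "b")}, "r")
        initialize_assignments(tree)
        aln = build_multiple_alignment(tree)
        assert len(aln.row_order) == 3
        gap_cols = [c for c in range(aln.length)
                    if any(aln.rows[r][c] is None for r in aln.row_order)]
        assert len(gap_cols) == 1

    def test_rows_preserve_genomes_and_no_empty_columns(self):
        params = SimulationParams(n=12, sigma=6, l=2, model="dup_singleloss",
                                  seed=21)
        inst = simulate_tree(5, params)
        tree, _ = run_steinerization(inst.tree, CostScheme.dup_singleloss())
        aln = build_multiple_alignment(tree)
        assert set(aln.row_order) == set(tree.nodes)
        for nid, node in tree.nodes.items():
            assert aln.ungapped(nid).genes == node.genome.genes
        for c in range(aln.length):
            assert any(aln.rows[r][c] is not None for r in aln.row_order)
        assert aln.length >= max(len(n.genome) for n in tree.nodes.values())
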