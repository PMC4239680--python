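"""Simulator: determinism, event statistics, ground-truth replay."""

import random

import pytest

from orderalign.model import DUP, LOSS, replay_history
from orderalign.simulate import (SimulationParams, apply_moves,
                                 evaluation_metrics, geometric, random_genome,
                                 simulate_star, simulate_tree)


class TestRandomGenome:
    def test_empty(self, rng):
        assert len(random_genome(0, 5, rng)) == 0

    def test_reproducible(self):
        a = random_genome(50, 10, random.Random(42))
        b = random_genome(50, 10, random.Random(42))
        assert a.genes == b.genes

    def test_family_multiplicity(self):
        g = random_genome(1000, 50, random.Random(1))
        fams = {}
        for gene in g:
            fams[gene.family] = fams.get(gene.family, 0) + 1
        mean = sum(fams.values()) / 50
        assert 15 < mean < 25  # expected multiplicity n/sigma = 20

    def test_rejects_zero_alphabet(self, rng):
        with pytest.raises(ValueError):
            random_genome(3, 0, rng)


class TestApplyMoves:
    def test_zero_moves(self, rng):
        params = SimulationParams(n=5, sigma=3, l=0)
        g = random_genome(5, 3, rng)
        out, hist = apply_moves(g, 0, params, rng)
        assert out.genes == g.genes and hist == []

    def test_geometric_mean_is_two(self):
        rng = random.Random(3)
        draws = [geometric(0.5, rng) for _ in range(100_000)]
        assert abs(sum(draws) / len(draws) - 2.0) < 0.05

    def test_single_gene_losses_only(self, rng):
        params = SimulationParams(n=20, sigma=10, l=30, model="dup_singleloss")
        g = random_genome(20, 10, rng)
        _, hist = apply_moves(g, 30, params, rng)
        assert all(op.length == 1 for op in hist if op.kind == LOSS)

    def test_history_replays(self, rng):
        params = SimulationParams(n=15, sigma=6, l=10, model="dup_singleloss")
        g = random_genome(15, 6, rng)
        out, hist = apply_moves(g, 10, params, rng)
        assert replay_history(g, hist).genes == out.genes

    def test_signed_model_emits_reversals(self):
        rng = random.Random(5)
        params = SimulationParams(n=30, sigma=10, l=60,
                                  model="dup_loss_reversal")
        g = random_genome(30, 10, rng)
        _, hist = apply_moves(g, 60, params, rng)
        kinds = {op.kind for op in hist}
        assert "reversal" in kinds


class TestSimulateTree:
    def test_branch_count_and_truth(self):
        params = SimulationParams(n=20, sigma=10, l=2, seed=9)
        inst = simulate_tree(12, params)
        # a rooted binary tree with 12 leaves has 2*12 - 2 branches
        assert len(inst.histories) == 22
        assert all(c == 2 for c in inst.true_counts.values())
        for child_id, hist in inst.histories.items():
            node = inst.tree.nodes[child_id]
            got = replay_history(node.parent.genome.with_id(child_id), hist)
            assert got.genes == node.genome.genes

    def test_bitwise_reproducible(self):
        a = simulate_tree(6, SimulationParams(n=15, sigma=8, l=1, seed=77))
        b = simulate_tree(6, SimulationParams(n=15, sigma=8, l=1, seed=77))
        assert all(a.tree.nodes[k].genome.genes == b.tree.nodes[k].genome.genes
                   for k in a.tree.nodes)

    def test_l_zero_identical_genomes(self):
        inst = simulate_tree(3, SimulationParams(n=10, sigma=5, l=0, seed=1))
        root = inst.tree.root.genome.genes
        assert all(n.genome.genes == root for n in inst.tree.nodes.values())


class TestSimulateStar:
    def test_each_branch_carries_l_events(self):
        inst, truth = simulate_star(SimulationParams(n=20, sigma=10, l=3, seed=4))
        assert {len(h) for h in truth.values()} == {3}

    def test_truth_replays(self):
        inst, truth = simulate_star(SimulationParams(n=20, sigma=10, l=2, seed=5))
        m = replay_history(inst.A, truth["M"])
        assert replay_history(m.with_id("X"), truth["X"]).genes == inst.X.genes
        assert replay_history(m.with_id("Y"), truth["Y"]).genes == inst.Y.genes


class TestEvaluationMetrics:
    def test_exact_match(self):
        assert evaluation_metrics(100, 100) == (0.0, None)

    def test_error_formula(self):
        err, _ = evaluation_metrics(101, 100)
        assert err == pytest.approx(1 / 101)

    def test_accuracy_formula(self):
        _, acc = evaluation_metrics(10, 10, nb_opt=48, total=50)
        assert acc == pytest.approx(0.96)

    def test_zero_inferred_with_nonzero_opt_rejected(self):
        with pytest.raises(ValueError):
            evaluation_metrics(0, 3)
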