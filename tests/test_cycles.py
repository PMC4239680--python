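"""Overlap cycles: detection on the duplication overlap graph, and repair."""

import pytest

from orderalign.cycles import (UndecomposableError, build_overlap_graph,
                               find_cycles, min_decomposition, resolve_cycles)
from orderalign.model import (DUP, LOSS, AlignOp, LabeledAlignment,
                              StarInstance, labeling_cost, validate_alignment)

from conftest import go

PK = lambda a, b: frozenset((a, b))


def _one_row(text, ops):
    return LabeledAlignment(rows={"X": go(text).genes}, row_order=["X"], ops=ops)


class TestOverlapGraph:
    def test_ancestor_sourced_ops_excluded(self):
        ops = [AlignOp(DUP, (0, 2), "X", frozenset({PK("A", "X")}),
                       ("A", (0, 2)))]
        aln = LabeledAlignment(rows={"A": go("ab").genes, "X": go("ab").genes},
                               row_order=["A", "X"], ops=ops,
                               ancestors=frozenset({"A"}))
        assert build_overlap_graph(aln).nx_graph.number_of_nodes() == 0

    def test_mutual_overlap_two_cycle(self):
        d1 = AlignOp(DUP, (0, 2), "X", frozenset({PK("X", "Y")}), ("X", (2, 4)))
        d2 = AlignOp(DUP, (2, 4), "X", frozenset({PK("X", "Y")}), ("X", (0, 2)))
        g = build_overlap_graph(_one_row("abab", [d1, d2]))
        assert g.nx_graph.number_of_nodes() == 2
        assert g.nx_graph.number_of_edges() == 2
        cycles = find_cycles(g)
        assert len(cycles) == 1 and len(cycles[0]) == 2

    def test_chain_without_cycle(self):
        d1 = AlignOp(DUP, (2, 4), "X", frozenset({PK("X", "Y")}), ("X", (0, 2)))
        g = build_overlap_graph(_one_row("abab", [d1]))
        assert find_cycles(g) == []


class TestMinDecomposition:
    @pytest.mark.parametrize("z,a,nparts", [
        ("abde", "abcde", 2),   # "ab" + "de"
        ("cde", "abcde", 1),
        ("ace", "abcde", 3),    # no 2-gene substring of Z occurs in A
    ])
    def test_part_counts(self, z, a, nparts):
        parts = min_decomposition(go(z).genes, go(a))
        assert len(parts) == nparts
        assert tuple(g for p in parts for g in p) == go(z).genes

    def test_undecomposable(self):
        with pytest.raises(UndecomposableError):
            min_decomposition(go("axb").genes, go("ab"))

    def test_agrees_with_greedy_on_factor_closed_sets(self, rng):
        """Shortest-path counts match greedy leftmost-longest (optimal for
        factor-closed piece sets) on random strings."""
        for _ in range(50):
            a = go("".join(rng.choice("abc") for _ in range(rng.randint(1, 8))))
            fams = sorted({g.family for g in a.genes})
            z = go("".join(rng.choice(fams) for _ in range(rng.randint(1, 6))))
            try:
                parts = min_decomposition(z.genes, a)
            except UndecomposableError:
                continue
            # greedy leftmost-longest
            subs = {a.genes[i:j] for i in range(len(a))
                    for j in range(i + 1, len(a) + 1)}
            greedy, u = 0, 0
            while u < len(z):
                v = max(w for w in range(u + 1, len(z) + 1)
                        if z.genes[u:w] in subs)
                greedy += 1
                u = v
            assert len(parts) == greedy


class TestResolveCycles:
    def _doubly_duplicated_instance(self):
        """Three-row labeling in which two same-content duplications source
        each other (the classic infeasible labeling of a doubly repeated
        segment)."""
        A = go("abcde", "A")
        X = go("acdeabdeabde", "X")
        Y = go("acde", "Y")
        rows = {
            "A": (A[0], A[1], A[2], A[3], A[4]) + (None,) * 8,
            "X": (X[0], None) + tuple(X[1:12]),
            "Y": (Y[0], None, Y[1], Y[2], Y[3]) + (None,) * 8,
        }
        ops = [
            AlignOp(LOSS, (1, 2), "M", frozenset({PK("A", "X"), PK("A", "Y")})),
            AlignOp(DUP, (5, 9), "X", frozenset({PK("A", "X"), PK("X", "Y")}),
                    ("X", (8, 12))),
            AlignOp(DUP, (9, 13), "X", frozenset({PK("A", "X"), PK("X", "Y")}),
                    ("X", (4, 8))),
        ]
        aln = LabeledAlignment(rows=rows, row_order=["A", "X", "Y"], ops=ops,
                               ancestors=frozenset({"A"}))
        assert validate_alignment(aln) == []
        return aln, StarInstance(A, X, Y)

    def test_feasible_input_unchanged(self):
        aln, inst = self._doubly_duplicated_instance()
        acyclic = LabeledAlignment(rows=dict(aln.rows),
                                   row_order=list(aln.row_order),
                                   ops=[aln.ops[0]], ancestors=aln.ancestors)
        out = resolve_cycles(acyclic, inst)
        assert out.ops == acyclic.ops

    def test_repair_yields_loss_plus_two_duplications(self):
        """The doubly-duplicated segment is relabeled as a loss in the
        sibling plus two duplications sourced in the grandparent."""
        aln, inst = self._doubly_duplicated_instance()
        assert len(find_cycles(build_overlap_graph(aln))) == 1
        out = resolve_cycles(aln, inst)
        assert find_cycles(build_overlap_graph(out)) == []
        assert validate_alignment(out) == []
        center_dups = [o for o in out.ops
                       if o.kind == DUP and o.branch == "M"]
        sibling_losses = [o for o in out.ops
                          if o.kind == LOSS and o.branch == "Y"]
        assert len(center_dups) == 2       # "ab" + "de", each occurring in A
        assert len(sibling_losses) == 1
        assert all(o.source[0] == "A" for o in center_dups)

    def test_repair_cost_arithmetic(self, unit_costs):
        """Cost increase equals c_L(|Z|) + sum of part costs - c_D(|Z|)."""
        aln, inst = self._doubly_duplicated_instance()
        before = labeling_cost(aln, unit_costs)
        out = resolve_cycles(aln, inst)
        after = labeling_cost(out, unit_costs)
        # one duplication (cost 1) replaced by a loss (1) and 2 parts (2)
        assert after - before == 1 + 2 - 1

    def test_cycle_members_are_duplications_on_backtracked_labelings(self):
        from orderalign.median import backtrack, compute_dp
        from orderalign.simulate import SimulationParams, simulate_star
        for seed in range(25):
            params = SimulationParams(n=8, sigma=3, l=2,
                                      model="dup_singleloss", seed=seed)
            inst, _ = simulate_star(params)
            aln = backtrack(compute_dp(inst), inst)
            for cycle in find_cycles(build_overlap_graph(aln)):
                assert all(op.kind == DUP for op in cycle)

    def test_resolution_always_feasible_on_simulated_suite(self):
        from orderalign.median import backtrack, compute_dp
        from orderalign.simulate import SimulationParams, simulate_star
        for seed in range(25):
            params = SimulationParams(n=10, sigma=4, l=3,
                                      model="dup_singleloss", seed=seed)
            inst, _ = simulate_star(params)
            aln = backtrack(compute_dp(inst), inst)
            out = resolve_cycles(aln, inst)
            assert find_cycles(build_overlap_graph(out)) == []
            assert validate_alignment(out) == []
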