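"""The 3-star dynamic program: recurrences, backtracking, full pipeline."""

import pytest

from orderalign.cycles import build_overlap_graph, find_cycles
from orderalign.median import (backtrack, compute_dp, evaluate_cases,
                               extract_center, solve_star)
from orderalign.model import (CostScheme, StarInstance, labeling_cost,
                              replay_history, validate_alignment)
from orderalign.oracle import exact_star_cost
from orderalign.simulate import SimulationParams, simulate_star

from conftest import go


def star(a, x, y, costs=None):
    return StarInstance(go(a), go(x), go(y), costs or CostScheme.unit())


class TestEvaluateCases:
    def test_match_column(self):
        table = compute_dp(star("a", "a", "a"))
        cands = evaluate_cases(1, 1, 1, table)
        assert ("match", 1, 0.0) in cands

    def test_reversal_above_center(self):
        # X = Y = reverse of A: one reversal of length 2
        inst = star("ab", "-b-a", "-b-a")
        table = compute_dp(inst)
        assert table.final_cost() == 1
        cands = evaluate_cases(2, 2, 2, table)
        assert any(case == "rev_M" and m == 2 for case, m, _ in cands)

    def test_shared_duplication_candidate(self):
        inst = star("ab", "abab", "abab")
        table = compute_dp(inst)
        cands = evaluate_cases(2, 4, 4, table)
        dup_m = [c for c in cands if c[0] == "dup_M" and c[1] == 2]
        assert dup_m and dup_m[0][2] == 1.0  # C(2,2,2)=0 plus one duplication

    def test_three_distinct_symbols_column_inapplicable(self):
        # a column [a, x, y] of three distinct families admits no single-size
        # interpretation; no match/reversal case may fire
        inst = star("a", "b", "c")
        table = compute_dp(inst)
        cands = evaluate_cases(1, 1, 1, table)
        assert all(case not in ("match", "rev_M", "rev_X", "rev_Y")
                   for case, _, _ in cands)


class TestComputeDP:
    def test_empty_triple(self):
        assert compute_dp(star("", "", "")).final_cost() == 0

    def test_identical_triple(self):
        assert compute_dp(star("abc", "abc", "abc")).final_cost() == 0

    def test_worked_strings_finite(self):
        table = compute_dp(star("abcde", "acdeabdeabde", "acde"))
        assert 0 < table.final_cost() < table.sentinel


class TestBacktrack:
    def test_identical_triple_empty_labeling(self):
        inst = star("abc", "abc", "abc")
        aln = backtrack(compute_dp(inst), inst)
        assert aln.ops == [] and validate_alignment(aln) == []

    def test_shared_loss(self):
        inst = star("abc", "ac", "ac")
        aln = backtrack(compute_dp(inst), inst)
        assert [op.kind for op in aln.ops] == ["loss"]
        assert aln.ops[0].branch == "M"

    def test_shared_duplication(self):
        inst = star("ab", "abab", "abab")
        aln = backtrack(compute_dp(inst), inst)
        dups = [op for op in aln.ops if op.kind == "duplication"]
        assert len(dups) == 1 and dups[0].branch == "M"
        assert validate_alignment(aln) == []


class TestSolveStar:
    def test_identity(self):
        sol = solve_star(star("acde", "acde", "acde"))
        assert sol.cost == 0 and sol.center.genes == go("acde").genes

    def test_shared_duplication_center(self):
        # frozen from the exhaustive star oracle: optimum is one event
        assert exact_star_cost(go("ab"), go("abab"), go("abab")).cost == 1
        sol = solve_star(star("ab", "abab", "abab"))
        assert sol.cost == 1
        assert sol.center.genes == go("abab").genes

    def test_shared_loss_center(self):
        sol = solve_star(star("abc", "ac", "ac"))
        assert sol.cost == 1
        assert sol.center.genes == go("ac").genes
        assert [op.kind for op in sol.histories["M"]] == ["loss"]
        assert sol.histories["X"] == [] and sol.histories["Y"] == []

    def test_worked_strings_full_pipeline(self):
        inst = star("abcde", "acdeabdeabde", "acde")
        sol = solve_star(inst)
        assert replay_history(inst.A, sol.histories["M"]).genes == sol.center.genes
        assert replay_history(sol.center, sol.histories["X"]).genes == inst.X.genes
        assert replay_history(sol.center, sol.histories["Y"]).genes == inst.Y.genes
        assert find_cycles(build_overlap_graph(sol.alignment)) == []
        assert sol.cost >= exact_star_cost(inst.A, inst.X, inst.Y).cost

    def test_signed_reversal_instance(self):
        sol = solve_star(star("ab", "-b-a", "-b-a"))
        assert sol.cost == 1
        assert sol.center.genes == go("-b-a").genes

    def test_deterministic(self):
        a = solve_star(star("abcde", "acdeabdeabde", "acde"))
        b = solve_star(star("abcde", "acdeabdeabde", "acde"))
        assert a.cost == b.cost and a.center.genes == b.center.genes


class TestAgainstOracle:
    def test_never_beats_exact_and_mostly_matches(self):
        """Heuristic >= exact on every tiny simulated instance, equal on at
        least 90% of them."""
        total = eq = 0
        for seed in range(60):
            params = SimulationParams(n=5, sigma=3, l=1,
                                      model="dup_singleloss", seed=seed)
            inst, _ = simulate_star(params)
            opt = exact_star_cost(inst.A, inst.X, inst.Y, inst.costs).cost
            got = solve_star(inst).cost
            assert got >= opt - 1e-9
            total += 1
            eq += abs(got - opt) < 1e-9
        assert eq / total >= 0.90

    def test_histories_replay_on_simulated_suite(self):
        for seed in range(20):
            params = SimulationParams(n=8, sigma=4, l=2,
                                      model="dup_singleloss", seed=seed)
            inst, _ = simulate_star(params)
            sol = solve_star(inst)
            assert replay_history(inst.A, sol.histories["M"]).genes == sol.center.genes
            assert replay_history(sol.center, sol.histories["X"]).genes == inst.X.genes
            assert replay_history(sol.center, sol.histories["Y"]).genes == inst.Y.genes
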