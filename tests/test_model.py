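"""Core domain types: reversal, occurrence tests, history replay, labeling."""

import pytest
from hypothesis import given, settings, strategies as st

from orderalign.model import (DUP, LOSS, REV, AlignOp, CostScheme, Gene,
                              GeneOrder, LabeledAlignment, Operation,
                              labeling_cost, occurs_in, replay_history,
                              reverse_of, validate_alignment)

from conftest import go

genes = st.lists(
    st.builds(Gene, family=st.sampled_from("abc"), sign=st.sampled_from((1, -1))),
    max_size=8).map(tuple)


class TestReverseOf:
    def test_signed_example(self):
        assert reverse_of(go("abc").genes) == go("-c-b-a").genes

    def test_empty(self):
        assert reverse_of(()) == ()

    @settings(derandomize=True)
    @given(genes)
    def test_involution_and_length(self, seg):
        assert reverse_of(reverse_of(seg)) == seg
        assert len(reverse_of(seg)) == len(seg)


class TestOccursIn:
    @pytest.mark.parametrize("pattern,text,expected", [
        ("ab", "cabd", True),
        ("ab", "ba", False),
        ("a", "-ab", False),   # signed-exact: +a is not -a
        ("-a", "-ab", True),
    ])
    def test_forward(self, pattern, text, expected):
        assert occurs_in(go(pattern).genes, go(text)) is expected

    def test_forward_or_reverse(self):
        # "ab" reversed-with-flip occurs in "-b-a"
        assert not occurs_in(go("ab").genes, go("-b-a"))
        assert occurs_in(go("ab").genes, go("-b-a"), mode="forward_or_reverse")

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            occurs_in((), go("ab"))


class TestReplayHistory:
    def test_empty_history(self):
        assert replay_history(go("ab"), []).genes == go("ab").genes

    def test_duplication_inserts_copy(self):
        op = Operation(DUP, 2, source=("", (0, 2)), target=("", (2, 4)))
        assert replay_history(go("ab"), [op]).genes == go("abab").genes

    def test_loss_deletes(self):
        op = Operation(LOSS, 1, source=("", (1, 2)))
        assert replay_history(go("abcde"), [op]).genes == go("acde").genes

    def test_reversal_in_place(self):
        op = Operation(REV, 2, source=("", (1, 3)), target=("", (1, 3)))
        assert replay_history(go("abc"), [op]).genes == go("a-c-b").genes

    def test_out_of_range_rejected(self):
        op = Operation(LOSS, 2, source=("", (3, 5)))
        with pytest.raises(ValueError):
            replay_history(go("ab"), [op])

    @settings(derandomize=True, max_examples=40)
    @given(st.data())
    def test_length_accounting(self, data):
        """|result| = |start| + sum of dup lengths - sum of loss lengths."""
        import random
        seed = data.draw(st.integers(0, 10_000))
        rng = random.Random(seed)
        from orderalign.simulate import SimulationParams, apply_moves, random_genome
        params = SimulationParams(n=8, sigma=3, l=4, model="dup_singleloss")
        g = random_genome(8, 3, rng)
        out, hist = apply_moves(g, 4, params, rng)
        delta = sum(op.length if op.kind == DUP else -op.length
                    for op in hist if op.kind in (DUP, LOSS))
        assert len(out) == len(g) + delta


class TestCostScheme:
    def test_unit_counts_events(self):
        c = CostScheme.unit()
        assert c.cost(DUP, 5) == 1 and c.cost(LOSS, 3) == 1

    def test_singleloss_charges_per_gene(self):
        c = CostScheme.dup_singleloss()
        assert c.cost(LOSS, 4) == 4 and c.cost(DUP, 4) == 1

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            CostScheme.unit().cost(DUP, 0)


def _two_row(x, y, ops):
    return LabeledAlignment(rows={"X": x, "Y": y}, row_order=["X", "Y"], ops=ops)


class TestLabeledAlignment:
    def test_all_match_valid_and_costless(self, unit_costs):
        aln = _two_row(go("ab").genes, go("ab").genes, [])
        assert validate_alignment(aln) == []
        assert labeling_cost(aln, unit_costs) == 0

    def test_uncovered_gap_reported(self):
        aln = _two_row(go("ab").genes, (Gene("a"), None), [])
        assert any("gap pair" in v for v in validate_alignment(aln))

    def test_covered_match_reported(self):
        op = AlignOp(REV, (0, 1), "Y", frozenset({frozenset(("X", "Y"))}))
        aln = _two_row(go("ab").genes, go("ab").genes, [op])
        assert any("match" in v for v in validate_alignment(aln))

    def test_all_gap_column_reported(self):
        aln = _two_row((Gene("a"), None), (Gene("a"), None), [])
        assert any("all gaps" in v for v in validate_alignment(aln))

    def test_unit_cost_counts_operations(self, unit_costs):
        ops = [AlignOp(LOSS, (1, 2), "Y", frozenset({frozenset(("X", "Y"))})),
               AlignOp(REV, (0, 1), "Y", frozenset({frozenset(("X", "Y"))}))]
        aln = _two_row(go("ab").genes, (go("-a").genes[0], None), ops)
        assert labeling_cost(aln, unit_costs) == len(ops)

    def test_out_of_range_operation_rejected(self, unit_costs):
        op = AlignOp(LOSS, (1, 5), "Y", frozenset({frozenset(("X", "Y"))}))
        aln = _two_row(go("ab").genes, (Gene("a"), None), [op])
        with pytest.raises(ValueError):
            labeling_cost(aln, unit_costs)
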