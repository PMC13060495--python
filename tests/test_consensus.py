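"""Reciprocal-overlap consensus calling, checked against set-based oracles."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triocnv.consensus import (
    ConsensusParams,
    call_consensus,
    collapse_calls,
    filter_support,
    intersect_pairwise,
    merge_fragments,
    passes_reciprocal,
    reciprocal_overlap,
)
from triocnv.core import DEL, DUP, CnvCall, GenomicInterval, ToolCallset

from .conftest import as_rows, random_instance
from .oracles import base_count_overlap_fractions, brute_force_consensus


def _call(tool, chrom, start, end, cnv_type=DEL, sample="s1"):
    return CnvCall(GenomicInterval(chrom, start, end), cnv_type, sample, tool)


def _sets(*tool_calls):
    out = []
    for tool, calls in tool_calls:
        out.append(ToolCallset(tool, "s1", [c for c in calls]))
    return out


class TestReciprocalOverlap:
    def test_identical_intervals(self):
        a = GenomicInterval("1", 100, 200)
        assert reciprocal_overlap(a, a) == (1.0, 1.0)

    def test_disjoint_intervals(self):
        a, b = GenomicInterval("1", 0, 100), GenomicInterval("1", 200, 300)
        assert reciprocal_overlap(a, b) == (0.0, 0.0)

    def test_different_chromosomes(self):
        a, b = GenomicInterval("1", 0, 100), GenomicInterval("2", 0, 100)
        assert reciprocal_overlap(a, b) == (0.0, 0.0)

    def test_half_overlap_matches_base_counting(self):
        a, b = GenomicInterval("1", 100, 200), GenomicInterval("1", 150, 250)
        assert reciprocal_overlap(a, b) == (0.5, 0.5)
        assert reciprocal_overlap(a, b) == base_count_overlap_fractions(
            ("1", 100, 200), ("1", 150, 250)
        )

    @given(
        sa=st.integers(0, 500), la=st.integers(1, 200),
        sb=st.integers(0, 500), lb=st.integers(1, 200),
    )
    @settings(max_examples=300, derandomize=True)
    def test_fractions_match_base_counting_oracle(self, sa, la, sb, lb):
        a = GenomicInterval("1", sa, sa + la)
        b = GenomicInterval("1", sb, sb + lb)
        fa, fb = reciprocal_overlap(a, b)
        ofa, ofb = base_count_overlap_fractions(("1", sa, sa + la), ("1", sb, sb + lb))
        assert fa == pytest.approx(ofa) and fb == pytest.approx(ofb)

    @given(
        sa=st.integers(0, 500), la=st.integers(1, 200),
        sb=st.integers(0, 500), lb=st.integers(1, 200),
    )
    @settings(max_examples=200, derandomize=True)
    def test_symmetry(self, sa, la, sb, lb):
        a = GenomicInterval("1", sa, sa + la)
        b = GenomicInterval("1", sb, sb + lb)
        assert reciprocal_overlap(a, b) == tuple(reversed(reciprocal_overlap(b, a)))

    def test_chr_prefix_normalised_for_comparison(self):
        a = GenomicInterval("chr1", 0, 100)
        b = GenomicInterval("1", 0, 100)
        assert reciprocal_overlap(a, b) == (1.0, 1.0)


class TestPassesReciprocal:
    def test_boundary_is_inclusive(self):
        a, b = GenomicInterval("1", 100, 200), GenomicInterval("1", 150, 250)
        assert passes_reciprocal(a, b, 0.5)

    def test_one_sided_containment_fails(self):
        a, b = GenomicInterval("1", 0, 1000), GenomicInterval("1", 0, 100)
        assert reciprocal_overlap(a, b) == (0.1, 1.0)
        assert not passes_reciprocal(a, b, 0.5)

    def test_identity_passes_at_full_fraction(self):
        a = GenomicInterval("1", 7, 19)
        assert passes_reciprocal(a, a, 1.0)

    def test_invalid_fraction_rejected(self):
        a = GenomicInterval("1", 0, 10)
        with pytest.raises(ValueError):
            passes_reciprocal(a, a, 0.0)


class TestIntersectPairwise:
    def test_identical_calls_give_one_fragment(self, params):
        sets = _sets(("A", [_call("A", "1", 100, 200)]), ("B", [_call("B", "1", 100, 200)]))
        frags = intersect_pairwise(sets, params)
        assert len(frags) == 1
        assert (frags[0].interval.start, frags[0].interval.end) == (100, 200)
        assert frags[0].tool_pair == frozenset({"A", "B"})

    def test_del_never_pairs_with_dup(self, params):
        sets = _sets(
            ("A", [_call("A", "1", 100, 200, DEL)]),
            ("B", [_call("B", "1", 100, 200, DUP)]),
        )
        assert intersect_pairwise(sets, params) == []

    def test_three_tool_chain_example(self, params):
        # A=[0,100) B=[40,140) C=[80,180): (A,B) and (B,C) share 60 bases
        # (0.6 each), (A,C) shares 20 (0.2) and fails at f=0.5
        sets = _sets(
            ("A", [_call("A", "1", 0, 100)]),
            ("B", [_call("B", "1", 40, 140)]),
            ("C", [_call("C", "1", 80, 180)]),
        )
        frags = intersect_pairwise(sets, params)
        spans = sorted((fr.interval.start, fr.interval.end) for fr in frags)
        assert spans == [(40, 100), (80, 140)]

    def test_mismatched_sample_ids_error(self, params):
        sets = [
            ToolCallset("A", "s1", [_call("A", "1", 0, 100)]),
            ToolCallset("B", "s2", [_call("B", "1", 0, 100, sample="s2")]),
        ]
        with pytest.raises(ValueError, match="sample"):
            intersect_pairwise(sets, params)

    def test_fragment_contained_in_both_sources(self, rng, params):
        for _ in range(20):
            callsets = random_instance(rng, max_calls=40)
            for fr in intersect_pairwise(callsets, params):
                for src in fr.source_calls:
                    assert fr.interval.start >= src.interval.start
                    assert fr.interval.end <= src.interval.end
                    assert fr.cnv_type == src.cnv_type

    def test_within_tool_duplicates_collapse_to_one_supporter(self, params):
        # tool A emits the same event twice; support must still be {A, B}, not 3 tools
        sets = _sets(
            ("A", [_call("A", "1", 0, 100), _call("A", "1", 10, 110)]),
            ("B", [_call("B", "1", 0, 100)]),
        )
        cons = call_consensus(sets, params)
        assert len(cons) == 1
        assert cons[0].tools == frozenset({"A", "B"})


class TestMergeFragments:
    def test_overlapping_fragments_merge_with_tool_union(self, params):
        sets = _sets(
            ("A", [_call("A", "1", 0, 100)]),
            ("B", [_call("B", "1", 40, 140)]),
            ("C", [_call("C", "1", 80, 180)]),
        )
        cons = merge_fragments(intersect_pairwise(sets, params), params)
        assert len(cons) == 1
        assert (cons[0].interval.start, cons[0].interval.end) == (40, 140)
        assert cons[0].tools == frozenset({"A", "B", "C"})
        assert cons[0].n_tools == 3

    def test_types_never_merge(self, params):
        sets = _sets(
            ("A", [_call("A", "1", 0, 50, DEL), _call("A", "1", 0, 50, DUP)]),
            ("B", [_call("B", "1", 0, 50, DEL), _call("B", "1", 0, 50, DUP)]),
        )
        cons = merge_fragments(intersect_pairwise(sets, params), params)
        assert sorted(c.cnv_type for c in cons) == [DEL, DUP]

    def test_bookended_fragments_merge_at_gap_zero(self, params):
        sets = _sets(
            ("A", [_call("A", "1", 0, 50), _call("A", "1", 50, 100)]),
            ("B", [_call("B", "1", 0, 50), _call("B", "1", 50, 100)]),
        )
        cons = merge_fragments(intersect_pairwise(sets, params), params)
        assert len(cons) == 1
        assert (cons[0].interval.start, cons[0].interval.end) == (0, 100)
        # the set-based oracle agrees
        oracle = brute_force_consensus(as_rows(sets))
        assert [(c[1], c[2]) for c in oracle] == [(0, 100)]


class TestFilterSupport:
    def test_boundary_two_tools_retained(self, params):
        sets = _sets(("A", [_call("A", "1", 0, 100)]), ("B", [_call("B", "1", 0, 100)]))
        assert len(call_consensus(sets, params)) == 1

    def test_single_tool_record_dropped_defensively(self, params):
        from triocnv.consensus import ConsensusCnv

        lone = ConsensusCnv(GenomicInterval("1", 0, 100), DEL, "s1", frozenset({"A"}))
        assert filter_support([lone], params) == []

    def test_min_tools_three_and_four_on_chain(self):
        sets = _sets(
            ("A", [_call("A", "1", 0, 100)]),
            ("B", [_call("B", "1", 40, 140)]),
            ("C", [_call("C", "1", 80, 180)]),
        )
        assert len(call_consensus(sets, ConsensusParams(min_tools=3))) == 1
        assert len(call_consensus(sets, ConsensusParams(min_tools=4))) == 0


class TestCallConsensus:
    def test_single_tool_raises(self, params):
        with pytest.raises(ValueError):
            call_consensus(_sets(("A", [_call("A", "1", 0, 100)])), params)

    def test_unanimous_tools_reproduce_the_callset(self, params):
        calls = [("1", 0, 100, DEL), ("1", 500, 700, DUP), ("2", 10, 60, DEL)]
        sets = [
            ToolCallset(t, "s1", [_call(t, c, s, e, ty) for c, s, e, ty in calls])
            for t in ("A", "B", "C", "D")
        ]
        cons = call_consensus(sets, params)
        assert len(cons) == 3
        assert all(c.n_tools == 4 for c in cons)
        got = sorted((c.interval.chrom, c.interval.start, c.interval.end, c.cnv_type) for c in cons)
        assert got == sorted(calls)

    def test_matches_set_based_oracle_on_random_instances(self, rng, params):
        for _ in range(50):
            callsets = random_instance(rng, max_calls=50)
            native = call_consensus(callsets, params)
            oracle = brute_force_consensus(as_rows(callsets))
            got = sorted(
                (c.interval.chrom, c.interval.start, c.interval.end, c.cnv_type, c.tools)
                for c in native
            )
            assert got == [(c, s, e, t, sup) for c, s, e, t, sup in oracle]

    def test_idempotence_on_consensus_output(self, rng, params):
        # feeding consensus regions back as calls from pseudo-tools
        # reproduces the same regions
        for _ in range(10):
            callsets = random_instance(rng, max_calls=40)
            cons = call_consensus(callsets, params)
            if not cons:
                continue
            pseudo = [
                ToolCallset(
                    f"p{i}", "s1",
                    [CnvCall(c.interval, c.cnv_type, "s1", f"p{i}") for c in cons],
                )
                for i in range(2)
            ]
            again = call_consensus(pseudo, params)
            assert [(c.interval, c.cnv_type) for c in again] == [
                (c.interval, c.cnv_type) for c in cons
            ]

    def test_same_type_output_regions_disjoint(self, rng, params):
        for _ in range(20):
            cons = call_consensus(random_instance(rng, max_calls=60), params)
            by_key: dict = {}
            for c in cons:
                by_key.setdefault((c.interval.chrom, c.cnv_type), []).append(c.interval)
            for ivs in by_key.values():
                ivs.sort(key=lambda iv: iv.start)
                for a, b in zip(ivs, ivs[1:]):
                    assert a.end < b.start  # disjoint and not even bookended


class TestMonotonicity:
    def test_fragment_count_non_increasing_in_f(self, rng):
        for _ in range(10):
            callsets = random_instance(rng, max_calls=60)
            counts = [
                len(intersect_pairwise(callsets, ConsensusParams(reciprocal_fraction=f)))
                for f in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_consensus_count_non_increasing_in_min_tools(self, rng):
        for _ in range(10):
            callsets = random_instance(rng, max_calls=60)
            counts = [
                len(call_consensus(callsets, ConsensusParams(min_tools=m)))
                for m in (2, 3, 4)
            ]
            assert counts == sorted(counts, reverse=True)


def test_collapse_calls_unions_overlapping_same_type(params):
    cs = ToolCallset(
        "A", "s1",
        [_call("A", "1", 0, 100), _call("A", "1", 50, 150), _call("A", "1", 300, 400),
         _call("A", "1", 90, 120, DUP)],
    )
    merged = collapse_calls(cs)
    dels = [(c.interval.start, c.interval.end) for c in merged if c.cnv_type == DEL]
    assert sorted(dels) == [(0, 150), (300, 400)]
    assert sum(1 for c in merged if c.cnv_type == DUP) == 1
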