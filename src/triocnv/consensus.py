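"""Consensus CNV calling across multiple read-depth callers.

High-confidence CNVs are derived per sample in three steps: every pair of
callers is intersected under a reciprocal-overlap criterion (both calls
must share at least a fraction ``f`` of their own length, default 50%);
intersection fragments of the same CNV type are merged transitively
(bookended fragments merge at the default gap of 0); merged regions are
retained when supported by at least ``min_tools`` distinct callers
(default 2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .core import (
    CnvCall,
    GenomicInterval,
    ToolCallset,
    normalize_chrom,
    overlap_length,
)


@dataclass
class ConsensusParams:
    """Tunable thresholds of the consensus procedure.

    reciprocal_fraction
        Minimum reciprocal-overlap fraction ``f`` in (0, 1]; a pair of
        calls qualifies only when the shared length is at least ``f`` of
        BOTH lengths. Default 0.5.
    min_tools
        Minimum number of distinct supporting callers, >= 2. Default 2.
    merge_gap
        Maximum gap in bp between same-type fragments that still merge;
        0 merges bookended fragments. Default 0.
    """

    reciprocal_fraction: float = 0.5
    min_tools: int = 2
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.reciprocal_fraction <= 1.0:
            raise ValueError(
                f"reciprocal_fraction must be in (0,1]: {self.reciprocal_fraction}"
            )
        if self.min_tools < 2:
            raise ValueError(f"min_tools must be >= 2: {self.min_tools}")
        if self.merge_gap < 0:
            raise ValueError(f"merge_gap must be >= 0: {self.merge_gap}")


@dataclass(frozen=True)
class IntersectionFragment:
    """Overlap region of one qualifying pair of same-type calls."""

    interval: GenomicInterval
    cnv_type: str
    sample_id: str
    tool_pair: frozenset
    source_calls: tuple[CnvCall, CnvCall]

    @property
    def sort_key(self) -> tuple:
        return (*self.interval.sort_key, self.cnv_type, tuple(sorted(self.tool_pair)))


@dataclass
class ConsensusCnv:
    """A merged same-type region with its supporting-caller set."""

    interval: GenomicInterval
    cnv_type: str
    sample_id: str
    tools: frozenset
    fragments: tuple = ()

    @property
    def n_tools(self) -> int:
        return len(self.tools)

    @property
    def sort_key(self) -> tuple:
        return (*self.interval.sort_key, self.cnv_type)


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """Overlap length as a fraction of each interval's own length.

    Returns ``(L/size(a), L/size(b))`` where ``L`` is the shared length;
    ``(0.0, 0.0)`` when the intervals sit on different chromosomes.
    """
    length = overlap_length(a, b)
    return (length / a.size(), length / b.size())


def passes_reciprocal(a: GenomicInterval, b: GenomicInterval, f: float) -> bool:
    """True iff both overlap fractions reach ``f`` (inclusive)."""
    if not 0.0 < f <= 1.0:
        raise ValueError(f"f must be in (0,1]: {f}")
    fa, fb = reciprocal_overlap(a, b)
    return fa >= f and fb >= f


def _merge_interval_runs(
    intervals: list[GenomicInterval], gap: int
) -> list[list[int]]:
    """Group indices of sorted intervals into transitively merging runs."""
    runs: list[list[int]] = []
    cur: list[int] = []
    cur_end = -1
    for i, iv in enumerate(intervals):
        if cur and iv.start <= cur_end + gap:
            cur.append(i)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                runs.append(cur)
            cur = [i]
            cur_end = iv.end
    if cur:
        runs.append(cur)
    return runs


def collapse_calls(callset: ToolCallset, merge_gap: int = 0) -> ToolCallset:
    """Union-merge a single caller's overlapping same-type calls.

    Callers occasionally emit fragmented or duplicated segments for one
    event; collapsing them prevents one caller from being counted as two
    supporters of a consensus region. Scores are dropped on merged calls.
    """
    by_group: dict[tuple, list[CnvCall]] = {}
    for call in callset.calls:
        key = (normalize_chrom(call.interval.chrom), call.cnv_type)
        by_group.setdefault(key, []).append(call)
    merged: list[CnvCall] = []
    for calls in by_group.values():
        calls.sort(key=lambda c: (c.interval.start, c.interval.end))
        intervals = [c.interval for c in calls]
        for run in _merge_interval_runs(intervals, merge_gap):
            members = [calls[i] for i in run]
            if len(members) == 1:
                merged.append(members[0])
            else:
                iv = GenomicInterval(
                    members[0].interval.chrom,
                    min(m.interval.start for m in members),
                    max(m.interval.end for m in members),
                )
                merged.append(
                    CnvCall(iv, members[0].cnv_type, callset.sample_id, callset.tool_id)
                )
    return ToolCallset(callset.tool_id, callset.sample_id, merged)


def intersect_pairwise(
    callsets: list[ToolCallset], params: ConsensusParams | None = None
) -> list[IntersectionFragment]:
    """Intersect every unordered pair of callers for one sample.

    For each pair of same-type calls from two distinct callers that
    passes the reciprocal-overlap criterion, one fragment covering the
    shared region is emitted. DEL never pairs with DUP. Within-caller
    overlapping calls are collapsed first.
    """
    params = params or ConsensusParams()
    if len(callsets) < 2:
        raise ValueError("need call sets from at least 2 tools")
    sample_ids = {cs.sample_id for cs in callsets}
    if len(sample_ids) != 1:
        raise ValueError(f"call sets mix sample IDs: {sorted(sample_ids)}")
    tool_ids = [cs.tool_id for cs in callsets]
    if len(set(tool_ids)) != len(tool_ids):
        raise ValueError(f"duplicate tool IDs: {tool_ids}")

    collapsed = [collapse_calls(cs) for cs in callsets]
    fragments: list[IntersectionFragment] = []
    for cs_a, cs_b in itertools.combinations(collapsed, 2):
        for group_key, calls_a in _group_calls(cs_a).items():
            calls_b = _group_calls(cs_b).get(group_key, [])
            fragments.extend(
                _intersect_sorted(calls_a, calls_b, params.reciprocal_fraction)
            )
    fragments.sort(key=lambda fr: fr.sort_key)
    return fragments


def _group_calls(cs: ToolCallset) -> dict[tuple, list[CnvCall]]:
    groups: dict[tuple, list[CnvCall]] = {}
    for call in cs.calls:
        groups.setdefault(
            (normalize_chrom(call.interval.chrom), call.cnv_type), []
        ).append(call)
    return groups


def _intersect_sorted(
    calls_a: list[CnvCall], calls_b: list[CnvCall], f: float
) -> list[IntersectionFragment]:
    """Sweep two start-sorted same-chrom same-type call lists for pairs."""
    out: list[IntersectionFragment] = []
    j0 = 0
    for a in calls_a:
        for j in range(j0, len(calls_b)):
            b = calls_b[j]
            if b.interval.end <= a.interval.start:
                if j == j0:
                    j0 = j + 1
                continue
            if b.interval.start >= a.interval.end:
                break
            if passes_reciprocal(a.interval, b.interval, f):
                iv = GenomicInterval(
                    a.interval.chrom,
                    max(a.interval.start, b.interval.start),
                    min(a.interval.end, b.interval.end),
                )
                out.append(
                    IntersectionFragment(
                        iv,
                        a.cnv_type,
                        a.sample_id,
                        frozenset({a.tool_id, b.tool_id}),
                        (a, b),
                    )
                )
    return out


def merge_fragments(
    fragments: list[IntersectionFragment], params: ConsensusParams | None = None
) -> list[ConsensusCnv]:
    """Transitively merge same-type fragments into consensus regions.

    Fragments of the same chromosome and CNV type merge when they overlap
    or sit within ``merge_gap`` bp of each other; the consensus interval
    is the union span and its supporting set the union of the fragments'
    caller pairs. Different types never merge.
    """
    params = params or ConsensusParams()
    sample_ids = {fr.sample_id for fr in fragments}
    if len(sample_ids) > 1:
        raise ValueError(f"fragments mix sample IDs: {sorted(sample_ids)}")

    groups: dict[tuple, list[IntersectionFragment]] = {}
    for fr in fragments:
        groups.setdefault(
            (normalize_chrom(fr.interval.chrom), fr.cnv_type), []
        ).append(fr)

    out: list[ConsensusCnv] = []
    for frs in groups.values():
        frs.sort(key=lambda fr: (fr.interval.start, fr.interval.end))
        for run in _merge_interval_runs([fr.interval for fr in frs], params.merge_gap):
            members = tuple(frs[i] for i in run)
            tools = frozenset().union(*(fr.tool_pair for fr in members))
            iv = GenomicInterval(
                members[0].interval.chrom,
                min(fr.interval.start for fr in members),
                max(fr.interval.end for fr in members),
            )
            out.append(
                ConsensusCnv(iv, members[0].cnv_type, members[0].sample_id, tools, members)
            )
    out.sort(key=lambda c: c.sort_key)
    return out


def filter_support(
    consensus: list[ConsensusCnv], params: ConsensusParams | None = None
) -> list[ConsensusCnv]:
    """Retain regions supported by at least ``min_tools`` distinct callers."""
    params = params or ConsensusParams()
    return [c for c in consensus if c.n_tools >= params.min_tools]


def call_consensus(
    callsets: list[ToolCallset], params: ConsensusParams | None = None
) -> list[ConsensusCnv]:
    """Full consensus procedure: pairwise intersect, merge, support-filter."""
    params = params or ConsensusParams()
    fragments = intersect_pairwise(callsets, params)
    return filter_support(merge_fragments(fragments, params), params)
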