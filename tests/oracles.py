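"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's interval arithmetic: the
consensus oracle works on explicit base-coordinate sets (practical
because test instances use small coordinates), and the signed-rank
oracle enumerates all 2^n sign assignments.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def _runs(bases: set[int]) -> list[tuple[int, int]]:
    """Maximal contiguous runs of a base set as half-open intervals."""
    out = []
    for b in sorted(bases):
        if out and b == out[-1][1]:
            out[-1] = (out[-1][0], b + 1)
        else:
            out.append((b, b + 1))
    return out


def brute_force_consensus(call_rows, f=0.5, min_tools=2):
    """Set-based consensus reference.

    ``call_rows``: iterable of (tool, chrom, start, end, cnv_type).
    Returns a sorted list of (chrom, start, end, cnv_type, frozenset(tools)).
    Semantics: per-tool overlapping/bookended same-type calls collapse;
    every tool pair intersects (both calls must share >= f of their own
    bases); fragments of one type merge transitively (bookended merge);
    regions supported by >= min_tools distinct tools are kept.
    """
    # collapse within tool via base-set union
    per_tool: dict[tuple, set[int]] = {}
    for tool, chrom, start, end, cnv_type in call_rows:
        per_tool.setdefault((tool, chrom, cnv_type), set()).update(range(start, end))

    tools = sorted({k[0] for k in per_tool})
    keys = sorted({(k[1], k[2]) for k in per_tool})

    fragments: list[tuple[str, str, set[int], frozenset]] = []
    for chrom, cnv_type in keys:
        for ta, tb in itertools.combinations(tools, 2):
            runs_a = _runs(per_tool.get((ta, chrom, cnv_type), set()))
            runs_b = _runs(per_tool.get((tb, chrom, cnv_type), set()))
            for sa, ea in runs_a:
                set_a = set(range(sa, ea))
                for sb, eb in runs_b:
                    set_b = set(range(sb, eb))
                    inter = set_a & set_b
                    if not inter:
                        continue
                    if len(inter) / len(set_a) >= f and len(inter) / len(set_b) >= f:
                        fragments.append((chrom, cnv_type, inter, frozenset({ta, tb})))

    out = []
    for chrom, cnv_type in keys:
        frs = [fr for fr in fragments if fr[0] == chrom and fr[1] == cnv_type]
        if not frs:
            continue
        union: set[int] = set().union(*(fr[2] for fr in frs))
        for start, end in _runs(union):
            support = frozenset().union(
                *(fr[3] for fr in frs if min(fr[2]) >= start and max(fr[2]) < end)
            )
            if len(support) >= min_tools:
                out.append((chrom, start, end, cnv_type, support))
    out.sort()
    return out


def exhaustive_signed_rank_p(diffs) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Zero differences are discarded; returns (W, p). Only feasible for
    small n (2^n assignments).
    """
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    w_all = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    w_all = np.asarray(w_all)
    p_le = np.mean(w_all <= w_obs + 1e-9)
    p_ge = np.mean(w_all >= w_obs - 1e-9)
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))


def base_count_overlap_fractions(a, b) -> tuple[float, float]:
    """Reciprocal overlap fractions by explicit base membership counting."""
    chrom_a, sa, ea = a
    chrom_b, sb, eb = b
    if chrom_a != chrom_b:
        return 0.0, 0.0
    bases_a = set(range(sa, ea))
    bases_b = set(range(sb, eb))
    inter = len(bases_a & bases_b)
    return inter / len(bases_a), inter / len(bases_b)
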