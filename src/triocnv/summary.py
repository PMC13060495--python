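"""Cohort-level descriptive statistics for multi-caller CNV call sets.

Covers per-tool call counts by type, size-bin histograms (default bins
<1 kb, 1-100 kb, 100 kb-1 Mb, 1-10 Mb, >=10 Mb), the per-tool overlap
rate against the consensus set, a paired Wilcoxon signed-rank test of
deletion-vs-duplication count bias, and trio-cohort demographics.
Percentages follow the half-up, one-decimal rounding convention of
clinical cohort reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ConsensusCnv, ConsensusParams, passes_reciprocal
from .core import DEL, DUP, ToolCallset, TrioManifest


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (4.05 -> 4.1), unlike banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SizeBins:
    """Left-closed size bins defined by ordered bp thresholds."""

    edges: tuple = (1_000, 100_000, 1_000_000, 10_000_000)

    def __post_init__(self) -> None:
        self.edges = tuple(int(e) for e in self.edges)
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])) or not self.edges:
            raise ValueError(f"bin edges must be strictly increasing: {self.edges}")

    @property
    def labels(self) -> list[str]:
        def fmt(bp: int) -> str:
            for unit, div in (("Mb", 10**6), ("kb", 10**3)):
                if bp % div == 0 and bp >= div:
                    return f"{bp // div} {unit}"
            return f"{bp} bp"

        labels = [f"<{fmt(self.edges[0])}"]
        labels += [
            f"{fmt(a)}-{fmt(b)}" for a, b in zip(self.edges, self.edges[1:])
        ]
        labels.append(f">={fmt(self.edges[-1])}")
        return labels

    def assign(self, size: int) -> str:
        return self.labels[int(np.searchsorted(self.edges, size, side="right"))]


def count_by_tool_type(callsets: list[ToolCallset]) -> pd.DataFrame:
    """Per-tool DEL/DUP/total call counts (tools pooled across samples)."""
    tools: dict[str, dict[str, int]] = {}
    for cs in callsets:
        row = tools.setdefault(cs.tool_id, {DEL: 0, DUP: 0})
        for call in cs:
            row[call.cnv_type] += 1
    df = pd.DataFrame.from_dict(tools, orient="index", dtype=int)
    if df.empty:
        df = pd.DataFrame(columns=[DEL, DUP], dtype=int)
    df = df.reindex(columns=[DEL, DUP], fill_value=0).sort_index()
    df["total"] = df[DEL] + df[DUP]
    df.index.name = "tool"
    return df


def size_histogram(calls, bins: SizeBins | None = None) -> pd.Series:
    """Counts of calls per size bin; every call lands in exactly one bin."""
    bins = bins or SizeBins()
    counts = pd.Series(0, index=bins.labels, dtype=int)
    for call in calls:
        counts[bins.assign(call.interval.size())] += 1
    counts.index.name = "size_bin"
    return counts


def overlap_rate(
    tool: ToolCallset,
    consensus: list[ConsensusCnv],
    params: ConsensusParams | None = None,
    mode: str = "consensus",
    others: list[ToolCallset] | None = None,
) -> float:
    """Percentage of a tool's raw calls represented in the consensus set.

    A raw call counts as represented when at least one same-type
    consensus region matches it at the reciprocal-overlap threshold. The
    alternative ``mode="pairwise"`` scores agreement with any other
    tool's raw calls instead of the consensus. Rounded half-up to one
    decimal, matching the reporting convention.
    """
    params = params or ConsensusParams()
    if len(tool) == 0:
        raise ValueError(f"tool {tool.tool_id!r} has an empty call set")
    if mode == "consensus":
        targets = consensus
    elif mode == "pairwise":
        if not others:
            raise ValueError("pairwise mode requires the other tools' call sets")
        targets = [c for cs in others if cs.tool_id != tool.tool_id for c in cs]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_hit = 0
    for call in tool:
        for t in targets:
            if t.cnv_type == call.cnv_type and passes_reciprocal(
                call.interval, t.interval, params.reciprocal_fraction
            ):
                n_hit += 1
                break
    return round_half_up(100.0 * n_hit / len(tool), 1)


@dataclass
class SignedRankResult:
    n_pairs: int            # pairs with a nonzero difference
    statistic: float        # W = sum of positive-difference ranks
    p_two_sided: float
    degenerate: bool = False
    method: str = "exact"


def _exact_signed_rank_p(ranks: np.ndarray, w: float) -> float:
    """Exact two-sided p for W under random signs, ties allowed.

    Mid-ranks are doubled to integers and the null distribution of the
    doubled positive-rank sum is built by dynamic-programming
    convolution over the 2^n equiprobable sign assignments.
    """
    doubled = np.rint(ranks * 2).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w * 2))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return min(1.0, 2.0 * min(p_le, p_ge))


def deldup_signed_rank(
    per_sample_counts, zero_method: str = "wilcox"
) -> SignedRankResult:
    """Paired Wilcoxon signed-rank test of per-sample DEL vs DUP counts.

    Differences ``n_del - n_dup`` are ranked by absolute value with
    mid-ranks on ties; W is the positive-rank sum. Zero differences are
    discarded (``zero_method="wilcox"``, the classic convention) or kept
    in the ranking and dropped from W (``"pratt"``). The two-sided p is
    exact for up to 25 nonzero pairs and a tie-corrected normal
    approximation beyond that. All-zero differences give the degenerate
    result p = 1.
    """
    pairs = list(per_sample_counts)
    if not pairs:
        raise ValueError("need at least one (n_del, n_dup) pair")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    diffs = np.asarray([float(d) - float(u) for d, u in pairs])
    nonzero = diffs[diffs != 0]
    n = len(nonzero)
    if n == 0:
        return SignedRankResult(0, 0.0, 1.0, degenerate=True, method="degenerate")

    if zero_method == "wilcox":
        ranked = nonzero
        all_ranks = stats.rankdata(np.abs(ranked))
        ranks = all_ranks
        signs = ranked > 0
    else:  # pratt: rank including zeros, drop zero ranks from both sums
        all_ranks = stats.rankdata(np.abs(diffs))
        keep = diffs != 0
        ranks = all_ranks[keep]
        signs = diffs[keep] > 0

    w = float(ranks[signs].sum())
    if n <= 25:
        p = _exact_signed_rank_p(ranks, w)
        method = "exact"
    else:
        # each rank enters W independently with prob 1/2, so
        # E[W] = sum(r)/2 and Var[W] = sum(r^2)/4; with mid-ranks this
        # equals the classic n(n+1)(2n+1)/24 minus the tie correction
        mu = ranks.sum() / 2.0
        var = float((ranks**2).sum()) / 4.0
        if var <= 0:
            return SignedRankResult(n, w, 1.0, degenerate=True, method="degenerate")
        z = (w - mu) / np.sqrt(var)
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
        method = "normal"
    return SignedRankResult(n, w, float(p), method=method)


def cohort_demographics(
    manifest: list[TrioManifest], phenotypes: pd.DataFrame
) -> dict:
    """Summarise a trio cohort and its proband phenotypes.

    ``phenotypes`` needs columns sample_id, sex, subphenotype covering
    every proband. Returns trio/individual counts, proband counts per
    sex, and within-sex subphenotype percentages (half-up, one decimal).
    """
    if not manifest:
        raise ValueError("empty trio manifest")
    seen = set()
    for t in manifest:
        if t.trio_id in seen:
            raise ValueError(f"duplicate trio_id {t.trio_id!r}")
        seen.add(t.trio_id)
    required = {"sample_id", "sex", "subphenotype"}
    missing = required - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns {sorted(missing)}")
    pheno = phenotypes.set_index("sample_id")
    for t in manifest:
        if t.proband_id not in pheno.index:
            raise ValueError(
                f"trio {t.trio_id!r}: proband {t.proband_id!r} missing from phenotype table"
            )
    probands = pheno.loc[[t.proband_id for t in manifest]]
    by_sex = probands.groupby("sex").size().to_dict()
    pct = {}
    for sex, group in probands.groupby("sex"):
        counts = group.groupby("subphenotype").size()
        pct[sex] = {
            pheno_name: round_half_up(100.0 * n / len(group), 1)
            for pheno_name, n in counts.items()
        }
    return {
        "n_trios": len(manifest),
        "n_individuals": 3 * len(manifest),
        "probands_by_sex": by_sex,
        "subphenotype_pct_by_sex": pct,
    }
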