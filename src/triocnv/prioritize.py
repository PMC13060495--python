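"""Prioritisation of annotated CNVs by ACMG class and Exomiser score.

The gates mirror clinical triage practice for structural variants: keep
regions whose ACMG class is VUS or worse (3, 4, 5 by default) and whose
phenotype-driven Exomiser score reaches at least 0.5; scores above 0.7
mark a CNV as highly specific for the patient phenotype. The 0.5 gate is
inclusive; the 0.7 tier boundary is strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .consensus import ConsensusParams, passes_reciprocal
from .core import AnnotationRecord, normalize_chrom
from .trio import InheritanceCall

logger = logging.getLogger(__name__)

ACMG_LABELS = {
    1: "benign",
    2: "likely benign",
    3: "VUS",
    4: "likely pathogenic",
    5: "pathogenic",
}

TIER_HIGH = "highly specific"
TIER_CONSISTENT = "consistent"
TIER_CANDIDATE = "candidate"


def acmg_label(acmg_class: int) -> str:
    """Human-readable label for an ACMG class 1-5."""
    try:
        return ACMG_LABELS[acmg_class]
    except KeyError:
        raise ValueError(f"ACMG class out of range 1-5: {acmg_class}") from None


@dataclass
class PrioritizationParams:
    exomiser_min: float = 0.5
    acmg_keep: frozenset = field(default_factory=lambda: frozenset({3, 4, 5}))
    high_specificity_cut: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 <= self.exomiser_min <= 1.0:
            raise ValueError(f"exomiser_min outside [0,1]: {self.exomiser_min}")
        self.acmg_keep = frozenset(self.acmg_keep)
        if not self.acmg_keep <= {1, 2, 3, 4, 5}:
            raise ValueError(f"acmg_keep outside 1-5: {sorted(self.acmg_keep)}")


def _tier(score: float | None, params: PrioritizationParams) -> str:
    if score is None or score < params.exomiser_min:
        return TIER_CANDIDATE
    if score > params.high_specificity_cut:
        return TIER_HIGH
    return TIER_CONSISTENT


def filter_priority(
    records: list[AnnotationRecord],
    params: PrioritizationParams | None = None,
    keep_candidates: bool = False,
) -> list[AnnotationRecord]:
    """Apply the ACMG and Exomiser gates; annotate kept records with a tier.

    Records with a missing or sub-threshold score are excluded unless
    ``keep_candidates`` is set, in which case they survive the score gate
    (not the ACMG gate) with tier ``"candidate"``.
    """
    params = params or PrioritizationParams()
    out: list[AnnotationRecord] = []
    for rec in records:
        if rec.acmg_class not in params.acmg_keep:
            continue
        score_ok = rec.exomiser_score is not None and rec.exomiser_score >= params.exomiser_min
        if not score_ok and not keep_candidates:
            continue
        out.append(replace(rec, tier=_tier(rec.exomiser_score, params)))
    return out


def build_report(
    priority: list[AnnotationRecord],
    inheritance: list[InheritanceCall],
    params: ConsensusParams | None = None,
) -> pd.DataFrame:
    """Join prioritised annotations with inheritance labels into a report.

    One row per prioritised CNV with columns patient_id, chr, start, end,
    size_bp, cnv_type, acmg_class, acmg_label, top_gene, genes,
    exomiser_score, tier, inheritance. Joining is by sample + type with
    exact coordinates, falling back to reciprocal overlap at ``f``; an
    unjoinable record is still emitted, with an empty inheritance label
    and a warning in the log.
    """
    params = params or ConsensusParams()
    by_sample: dict[str, list[InheritanceCall]] = {}
    for call in inheritance:
        by_sample.setdefault(call.cnv.sample_id, []).append(call)

    rows = []
    for rec in priority:
        label = ""
        candidates = [
            c for c in by_sample.get(rec.sample_id, []) if c.cnv.cnv_type == rec.cnv_type
        ]
        exact = [
            c for c in candidates
            if normalize_chrom(c.cnv.interval.chrom) == normalize_chrom(rec.interval.chrom)
            and c.cnv.interval.start == rec.interval.start
            and c.cnv.interval.end == rec.interval.end
        ]
        fuzzy = exact or [
            c for c in candidates
            if passes_reciprocal(c.cnv.interval, rec.interval, params.reciprocal_fraction)
        ]
        if fuzzy:
            label = fuzzy[0].label
        else:
            logger.warning(
                "no inheritance record joins annotation %s:%d-%d %s (%s)",
                rec.interval.chrom, rec.interval.start, rec.interval.end,
                rec.cnv_type, rec.sample_id,
            )
        rows.append(
            {
                "patient_id": rec.sample_id,
                "chr": rec.interval.chrom,
                "start": rec.interval.start,
                "end": rec.interval.end,
                "size_bp": rec.interval.size(),
                "cnv_type": rec.cnv_type,
                "acmg_class": rec.acmg_class,
                "acmg_label": acmg_label(rec.acmg_class),
                "top_gene": rec.top_gene,
                "genes": ";".join(rec.genes),
                "exomiser_score": rec.exomiser_score,
                "tier": rec.tier,
                "inheritance": label,
            }
        )
    columns = [
        "patient_id", "chr", "start", "end", "size_bp", "cnv_type", "acmg_class",
        "acmg_label", "top_gene", "genes", "exomiser_score", "tier", "inheritance",
    ]
    report = pd.DataFrame(rows, columns=columns)
    logger.info(
        "%d prioritised records across %d distinct probands",
        len(report), report["patient_id"].nunique() if len(report) else 0,
    )
    return report
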