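"""De novo vs inherited classification of proband CNVs in case-parent trios.

A proband consensus CNV is *inherited* when a parental CNV of the same
type matches it under the reciprocal-overlap criterion (the same ``f``
used for consensus calling, default 0.5), and *de novo* otherwise. A
parental CNV of the opposite type never rescues a call from de novo
status, and a sub-threshold parental overlap still yields de novo — the
``parental_matches`` field is empty exactly when the label is de novo,
so borderline cases are visible to the user.
"""

from __future__ import annotations

from dataclasses import dataclass

from .consensus import ConsensusCnv, ConsensusParams, reciprocal_overlap
from .core import TrioManifest

DE_NOVO = "de_novo"
INHERITED_MATERNAL = "inherited_maternal"
INHERITED_PATERNAL = "inherited_paternal"
INHERITED_BOTH = "inherited_both"


@dataclass(frozen=True)
class ParentalMatch:
    """A qualifying parental CNV with its reciprocal-overlap fractions."""

    parent: str          # "mother" or "father"
    cnv: object          # the matching parental CNV record
    frac_proband: float  # overlap as fraction of the proband CNV
    frac_parent: float   # overlap as fraction of the parental CNV


@dataclass
class InheritanceCall:
    cnv: ConsensusCnv
    label: str
    parental_matches: tuple[ParentalMatch, ...] = ()


def _matches(proband_cnv, parental_cnvs, parent: str, f: float):
    out = []
    for p in parental_cnvs:
        if p.cnv_type != proband_cnv.cnv_type:
            continue
        fa, fb = reciprocal_overlap(proband_cnv.interval, p.interval)
        if fa >= f and fb >= f:
            out.append(ParentalMatch(parent, p, fa, fb))
    return out


def classify_trio(
    proband: list[ConsensusCnv],
    mother: list,
    father: list,
    params: ConsensusParams | None = None,
    manifest: TrioManifest | None = None,
) -> list[InheritanceCall]:
    """Label every proband CNV de novo or inherited by parental matching.

    ``mother`` and ``father`` may hold consensus records or raw calls —
    any record with ``interval`` and ``cnv_type`` qualifies. When a
    manifest is given, sample IDs of all three call lists are checked
    against their trio roles.
    """
    params = params or ConsensusParams()
    if manifest is not None:
        for calls, expected, role in (
            (proband, manifest.proband_id, "proband"),
            (mother, manifest.mother_id, "mother"),
            (father, manifest.father_id, "father"),
        ):
            bad = {c.sample_id for c in calls} - {expected}
            if bad:
                raise ValueError(
                    f"trio {manifest.trio_id!r}: {role} call set carries sample "
                    f"IDs {sorted(bad)}, expected {expected!r}"
                )
    f = params.reciprocal_fraction
    out: list[InheritanceCall] = []
    for cnv in proband:
        m = _matches(cnv, mother, "mother", f)
        p = _matches(cnv, father, "father", f)
        if m and p:
            label = INHERITED_BOTH
        elif m:
            label = INHERITED_MATERNAL
        elif p:
            label = INHERITED_PATERNAL
        else:
            label = DE_NOVO
        out.append(InheritanceCall(cnv, label, tuple(m + p)))
    return out


def denovo_rate(calls: list[InheritanceCall]) -> float:
    """Fraction of proband CNVs labelled de novo."""
    if not calls:
        raise ValueError("denovo_rate of an empty call list is undefined")
    return sum(1 for c in calls if c.label == DE_NOVO) / len(calls)
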