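"""Domain types for multi-caller CNV call sets in WES trios.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``, so the length of an event is always ``end - start``.
Chromosome names are stored verbatim; comparisons between records use a
normalised form (leading ``chr`` stripped, upper-cased) so that ``chr12``
and ``12`` refer to the same sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

DEL = "DEL"
DUP = "DUP"
CNV_TYPES = (DEL, DUP)

_TYPE_ALIASES = {
    "del": DEL,
    "deletion": DEL,
    "loss": DEL,
    "dup": DUP,
    "duplication": DUP,
    "gain": DUP,
}

_CN_RE = re.compile(r"^cn(\d+)$")


class CnvTypeError(ValueError):
    """Raised for a CNV-type token that maps to neither DEL nor DUP."""


def normalize_cnv_type(token: str) -> str:
    """Map a caller-specific CNV-type token to ``DEL`` or ``DUP``.

    Accepted case-insensitively: deletion/del/loss and copy-number codes
    below 2 (``CN0``, ``CN1``) map to DEL; duplication/dup/gain and codes
    above 2 map to DUP. ``CN2`` is diploid and therefore not a CNV.
    """
    low = token.strip().lower()
    if low in _TYPE_ALIASES:
        return _TYPE_ALIASES[low]
    m = _CN_RE.match(low)
    if m:
        cn = int(m.group(1))
        if cn < 2:
            return DEL
        if cn > 2:
            return DUP
        raise CnvTypeError(f"copy-number code {token!r} is diploid, not a CNV")
    raise CnvTypeError(f"unknown CNV type token: {token!r}")


def normalize_chrom(name: str) -> str:
    """Normalised chromosome name for comparisons: strip 'chr', upper-case."""
    n = name.strip()
    if n.lower().startswith("chr"):
        n = n[3:]
    n = n.upper()
    return "M" if n == "MT" else n


def chrom_sort_key(name: str) -> tuple:
    """Natural chromosome order: numeric ascending, then X, Y, M, then other."""
    n = normalize_chrom(name)
    if n.isdigit():
        return (0, int(n), "")
    special = {"X": 0, "Y": 1, "M": 2}
    if n in special:
        return (1, special[n], "")
    return (2, 0, n)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: [{self.start}, {self.end}) on {self.chrom}"
            )

    def size(self) -> int:
        return self.end - self.start

    @property
    def sort_key(self) -> tuple:
        return (*chrom_sort_key(self.chrom), self.start, self.end)

    def same_chrom(self, other: "GenomicInterval") -> bool:
        return normalize_chrom(self.chrom) == normalize_chrom(other.chrom)


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Shared length of two intervals in bp; 0 off-chromosome or disjoint."""
    if not a.same_chrom(b):
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class CnvCall:
    """One caller's CNV interval for one sample."""

    interval: GenomicInterval
    cnv_type: str
    sample_id: str
    tool_id: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"cnv_type must be DEL or DUP, got {self.cnv_type!r}")
        if not self.tool_id:
            raise ValueError("tool_id must be non-empty")

    @property
    def sort_key(self) -> tuple:
        return (*self.interval.sort_key, self.cnv_type)


@dataclass
class ToolCallset:
    """All CNV calls of one tool for one sample, kept sorted."""

    tool_id: str
    sample_id: str
    calls: list[CnvCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in self.calls:
            if c.tool_id != self.tool_id or c.sample_id != self.sample_id:
                raise ValueError(
                    f"call {c} does not belong to tool {self.tool_id!r} / "
                    f"sample {self.sample_id!r}"
                )
        self.calls = sorted(self.calls, key=lambda c: c.sort_key)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)


@dataclass(frozen=True)
class TrioManifest:
    """Sample identifiers of one case-parent trio."""

    trio_id: str
    proband_id: str
    mother_id: str
    father_id: str

    def __post_init__(self) -> None:
        ids = {self.proband_id, self.mother_id, self.father_id}
        if len(ids) != 3 or "" in ids:
            raise ValueError(
                f"trio {self.trio_id!r}: proband, mother and father IDs must be "
                "three distinct non-empty strings"
            )


@dataclass(frozen=True)
class AnnotationRecord:
    """External annotation attached to a CNV region.

    ``acmg_class`` is the 1-5 ACMG pathogenicity class (5 pathogenic,
    4 likely pathogenic, 3 VUS, 2 likely benign, 1 benign).
    ``exomiser_score`` is the phenotype-driven prioritisation score in
    [0, 1]; ``None`` marks a missing value.
    """

    interval: GenomicInterval
    cnv_type: str
    sample_id: str
    acmg_class: int
    exomiser_score: float | None
    genes: tuple[str, ...] = ()
    top_gene: str = ""
    tier: str | None = None

    def __post_init__(self) -> None:
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"cnv_type must be DEL or DUP, got {self.cnv_type!r}")
        if self.acmg_class not in (1, 2, 3, 4, 5):
            raise ValueError(f"ACMG class out of range 1-5: {self.acmg_class}")
        if self.exomiser_score is not None and not 0.0 <= self.exomiser_score <= 1.0:
            raise ValueError(f"Exomiser score outside [0,1]: {self.exomiser_score}")
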