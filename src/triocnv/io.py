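"""Readers and writers for the pipeline's plain-text dialects.

Three tab-separated formats are handled:

* call-set BED dialect — columns 1-4 chrom, start, end, cnv_type;
  optional columns 5-7 sample_id, tool_id, score; ``#`` and ``track``
  lines are comments;
* consensus BED dialect — columns 1-4 as above, column 5 the number of
  supporting callers, column 6 the comma-joined sorted caller IDs,
  optional column 7 the sample ID;
* trio manifest — header ``trio_id  proband_id  mother_id  father_id``;
* annotation tables — header-driven TSV in an AnnotSV-style layout with
  configurable column names.

Coordinates may carry thousands separators (``18,528,750``); they are
stripped on parse. Coordinates are recorded verbatim — the parser never
"corrects" a chromosome assignment or position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

from .consensus import ConsensusCnv
from .core import (
    AnnotationRecord,
    CnvCall,
    CnvTypeError,
    GenomicInterval,
    ToolCallset,
    TrioManifest,
    normalize_cnv_type,
)

_MISSING = {"", ".", "na", "nan", "none", "null"}


class CallsetParseError(ValueError):
    """A malformed record, reported with its file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _is_comment(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith("#") or s.startswith("track")


def _parse_coord(token: str, path, lineno: int, what: str) -> int:
    try:
        return int(token.replace(",", ""))
    except ValueError:
        raise CallsetParseError(path, lineno, f"non-integer {what}: {token!r}") from None


def read_callset(path, tool_id: str, sample_id: str) -> ToolCallset:
    """Read one caller's calls for one sample from the BED dialect.

    When columns 5/6 (sample, tool) are present in the file they must
    agree with the arguments. Calls are returned sorted by
    (chromosome natural order, start, end) regardless of file order.
    """
    path = Path(path)
    calls: list[CnvCall] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_comment(line):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 4:
                raise CallsetParseError(
                    path, lineno, f"expected >=4 tab-separated columns, got {len(cols)}"
                )
            chrom = cols[0].strip()
            start = _parse_coord(cols[1], path, lineno, "start")
            end = _parse_coord(cols[2], path, lineno, "end")
            if end <= start:
                raise CallsetParseError(path, lineno, f"end <= start: {start} {end}")
            try:
                cnv_type = normalize_cnv_type(cols[3])
            except CnvTypeError as exc:
                raise CallsetParseError(path, lineno, str(exc)) from None
            if len(cols) > 4 and cols[4].strip() and cols[4].strip() != sample_id:
                raise CallsetParseError(
                    path, lineno,
                    f"sample column {cols[4].strip()!r} != expected {sample_id!r}",
                )
            if len(cols) > 5 and cols[5].strip() and cols[5].strip() != tool_id:
                raise CallsetParseError(
                    path, lineno,
                    f"tool column {cols[5].strip()!r} != expected {tool_id!r}",
                )
            score = None
            if len(cols) > 6 and cols[6].strip().lower() not in _MISSING:
                try:
                    score = float(cols[6])
                except ValueError:
                    raise CallsetParseError(
                        path, lineno, f"non-numeric score: {cols[6]!r}"
                    ) from None
            calls.append(
                CnvCall(GenomicInterval(chrom, start, end), cnv_type, sample_id,
                        tool_id, score)
            )
    return ToolCallset(tool_id, sample_id, calls)


def write_callset(records, path) -> None:
    """Write CnvCall or ConsensusCnv records to the matching BED dialect."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            iv = rec.interval
            if isinstance(rec, ConsensusCnv):
                tools = ",".join(sorted(rec.tools))
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.cnv_type}\t"
                    f"{rec.n_tools}\t{tools}\t{rec.sample_id}\n"
                )
            else:
                score = "." if rec.score is None else repr(rec.score)
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.cnv_type}\t"
                    f"{rec.sample_id}\t{rec.tool_id}\t{score}\n"
                )


def read_consensus(path, sample_id: str | None = None) -> list[ConsensusCnv]:
    """Read consensus records; constituent fragments are not persisted."""
    path = Path(path)
    out: list[ConsensusCnv] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_comment(line):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 6:
                raise CallsetParseError(
                    path, lineno, f"expected >=6 columns in consensus dialect, got {len(cols)}"
                )
            iv = GenomicInterval(
                cols[0].strip(),
                _parse_coord(cols[1], path, lineno, "start"),
                _parse_coord(cols[2], path, lineno, "end"),
            )
            try:
                cnv_type = normalize_cnv_type(cols[3])
            except CnvTypeError as exc:
                raise CallsetParseError(path, lineno, str(exc)) from None
            n_tools = _parse_coord(cols[4], path, lineno, "n_tools")
            tools = frozenset(t for t in cols[5].split(",") if t)
            if len(tools) != n_tools:
                raise CallsetParseError(
                    path, lineno, f"n_tools {n_tools} != |{sorted(tools)}|"
                )
            sid = cols[6].strip() if len(cols) > 6 else (sample_id or "")
            out.append(ConsensusCnv(iv, cnv_type, sid, tools))
    out.sort(key=lambda c: c.sort_key)
    return out


def read_trio_manifest(path) -> list[TrioManifest]:
    """Read a trio manifest TSV (header: trio_id, proband_id, mother_id, father_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["trio_id", "proband_id", "mother_id", "father_id"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"trio manifest missing required column {col!r}")
    return [
        TrioManifest(r.trio_id, r.proband_id, r.mother_id, r.father_id)
        for r in df.itertuples()
    ]


def write_trio_manifest(trios: list[TrioManifest], path) -> None:
    pd.DataFrame(
        [
            {
                "trio_id": t.trio_id,
                "proband_id": t.proband_id,
                "mother_id": t.mother_id,
                "father_id": t.father_id,
            }
            for t in trios
        ]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class AnnotationColumns:
    """Column-name mapping for annotation TSVs (AnnotSV-style, configurable)."""

    sample: str = "Patient_ID"
    chrom: str = "Chr"
    start: str = "Start"
    end: str = "End"
    cnv_type: str = "CNV_Type"
    acmg: str = "ACMG_Class"
    exomiser: str = "Exomiser_Score"
    genes: str = "Genes"
    top_gene: str = "Top_Gene"

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AnnotationColumns":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown annotation column keys: {sorted(unknown)}")
        return cls(**mapping)


def read_annotations(
    path,
    columns: AnnotationColumns | None = None,
    gene_delimiter: str = ";",
) -> list[AnnotationRecord]:
    """Read an annotation TSV into :class:`AnnotationRecord` rows.

    Required columns: sample, chrom, start, end, cnv_type, acmg, exomiser.
    The genes and top-gene columns are optional; a missing Exomiser score
    (``NA``/empty) is kept as ``None`` and excluded later by the score
    gate rather than at parse time.
    """
    columns = columns or AnnotationColumns()
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = [
        columns.sample, columns.chrom, columns.start, columns.end,
        columns.cnv_type, columns.acmg, columns.exomiser,
    ]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"annotation table missing required column {col!r}")
    records: list[AnnotationRecord] = []
    for row in df.itertuples(index=False):
        vals = dict(zip(df.columns, row))
        iv = GenomicInterval(
            str(vals[columns.chrom]).strip(),
            int(str(vals[columns.start]).replace(",", "")),
            int(str(vals[columns.end]).replace(",", "")),
        )
        acmg = int(str(vals[columns.acmg]).strip())
        raw_score = str(vals[columns.exomiser]).strip().lower()
        score = None if raw_score in _MISSING else float(vals[columns.exomiser])
        if score is not None and math.isnan(score):
            score = None
        top_gene = ""
        if columns.top_gene in df.columns:
            tg = str(vals[columns.top_gene]).strip()
            top_gene = "" if tg.lower() in _MISSING else tg
        genes: tuple[str, ...] = ()
        if columns.genes in df.columns:
            raw = str(vals[columns.genes]).strip()
            if raw.lower() not in _MISSING:
                genes = tuple(g.strip() for g in raw.split(gene_delimiter) if g.strip())
        if not genes and top_gene:
            genes = (top_gene,)
        if not top_gene and genes:
            top_gene = genes[0]
        records.append(
            AnnotationRecord(
                iv,
                normalize_cnv_type(str(vals[columns.cnv_type])),
                str(vals[columns.sample]).strip(),
                acmg,
                score,
                genes,
                top_gene,
            )
        )
    return records
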