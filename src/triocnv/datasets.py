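"""Bundled worked-example tables.

Two small published report tables of de novo CNVs from a syndromic
orofacial-cleft trio cohort ship with the package as plain TSV; they
drive the worked example in the README and the prioritisation-gate
checks in the test suite.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import pandas as pd

from .core import AnnotationRecord
from .io import read_annotations

KNOWN_OFC_TABLE = "denovo_known_ofc_genes.tsv"
CANDIDATE_TABLE = "denovo_candidate_regions.tsv"


def dataset_path(name: str) -> Path:
    """Filesystem path of a bundled TSV."""
    return Path(str(files("triocnv").joinpath("data", name)))


def load_known_ofc_annotations() -> list[AnnotationRecord]:
    """De novo CNVs overlapping established craniofacial genes (10 rows)."""
    return read_annotations(dataset_path(KNOWN_OFC_TABLE))


def load_candidate_annotations() -> list[AnnotationRecord]:
    """De novo CNVs in candidate regions (14 rows; most scores unpublished)."""
    return read_annotations(dataset_path(CANDIDATE_TABLE))


def load_dataset_frame(name: str) -> pd.DataFrame:
    """Raw dataframe of a bundled table, printed size column included."""
    return pd.read_csv(dataset_path(name), sep="\t", comment="#", dtype=str)
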