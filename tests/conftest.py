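"""Shared fixtures and random-instance generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from triocnv.consensus import ConsensusParams
from triocnv.core import DEL, DUP, CnvCall, GenomicInterval, ToolCallset


def random_instance(
    rng: np.random.Generator,
    n_tools: int = 4,
    max_calls: int = 100,
    coord_max: int = 4000,
    max_size: int = 400,
) -> list[ToolCallset]:
    """A random multi-tool single-sample call instance with small coordinates.

    Coordinates are kept small so that set-based test oracles remain
    practical; mixed DEL/DUP types and two chromosomes are included.
    """
    tools = [f"t{i}" for i in range(n_tools)]
    n_calls = int(rng.integers(0, max_calls + 1))
    calls_per_tool: dict[str, list[CnvCall]] = {t: [] for t in tools}
    for _ in range(n_calls):
        tool = tools[rng.integers(0, n_tools)]
        chrom = str(rng.integers(1, 3))
        start = int(rng.integers(0, coord_max))
        size = int(rng.integers(1, max_size))
        cnv_type = DEL if rng.random() < 0.5 else DUP
        calls_per_tool[tool].append(
            CnvCall(GenomicInterval(chrom, start, start + size), cnv_type, "s1", tool)
        )
    return [ToolCallset(t, "s1", calls_per_tool[t]) for t in tools]


def as_rows(callsets: list[ToolCallset]) -> list[tuple]:
    """(tool, chrom, start, end, type) rows for the set-based oracle."""
    return [
        (cs.tool_id, c.interval.chrom, c.interval.start, c.interval.end, c.cnv_type)
        for cs in callsets
        for c in cs
    ]


@pytest.fixture
def params() -> ConsensusParams:
    return ConsensusParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
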