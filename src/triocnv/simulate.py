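"""Synthetic multi-caller CNV call sets for case-parent trios.

The simulator emulates the *output boundary* of WES read-depth CNV
callers — not reads or depth profiles. Ground-truth CNVs are drawn per
individual (log-uniform sizes, uniform placement on a small synthetic
genome), transmitted from parents to probands with Mendelian
bookkeeping, and then observed through four imperfect caller profiles
that differ in sensitivity, false-positive load, breakpoint jitter and
minimum detectable size. False positives are independent across callers
by default, which is precisely what makes a >=2-caller consensus
informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .consensus import ConsensusParams, call_consensus, reciprocal_overlap
from .core import DEL, DUP, CnvCall, GenomicInterval, ToolCallset, TrioManifest
from .trio import DE_NOVO, InheritanceCall, classify_trio

logger = logging.getLogger(__name__)

MATERNAL = "maternal"
PATERNAL = "paternal"
PARENTAL_OWN = "parental_own"

# minimum spacing between truth CNVs within an individual; keeps truth
# events from merging into one consensus region even after jitter
_TRUTH_BUFFER = 50_000
_MIN_CALL_SIZE = 50


@dataclass(frozen=True)
class TruthCnv:
    interval: GenomicInterval
    cnv_type: str
    sample_id: str
    origin: str  # de_novo, maternal, paternal, or parental_own


@dataclass
class TruthTable:
    records: list[TruthCnv] = field(default_factory=list)

    def for_sample(self, sample_id: str) -> list[TruthCnv]:
        return [r for r in self.records if r.sample_id == sample_id]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ToolProfile:
    """Error model of one emulated caller.

    ``sensitivity`` is either a scalar detection probability or a
    mapping from size-bin label (see :class:`~triocnv.summary.SizeBins`)
    to a probability. ``fp_calls_per_sample`` is the Poisson mean of
    spurious calls. ``jitter_sd`` (bp) is the s.d. of the rounded normal
    noise added to each breakpoint. Calls smaller than
    ``min_detectable_size`` are never emitted.
    """

    tool_id: str
    sensitivity: float | dict = 0.9
    fp_calls_per_sample: float = 2.0
    jitter_sd: float = 100.0
    min_detectable_size: int = _MIN_CALL_SIZE

    def sensitivity_for(self, size: int) -> float:
        if isinstance(self.sensitivity, dict):
            from .summary import SizeBins

            return float(self.sensitivity[SizeBins().assign(size)])
        return float(self.sensitivity)


def default_tool_profiles() -> list[ToolProfile]:
    """Four profiles qualitatively mirroring common WES CNV callers.

    The ExomeDepth-like profile calls most and agrees least; the
    cn.MOPS-like profile calls fewest, is most specific, and cannot see
    events under 1 kb; gCNV and CODEX sit between.
    """
    return [
        ToolProfile("exomedepth", 0.95, 12.0, 150.0, _MIN_CALL_SIZE),
        ToolProfile("gcnv", 0.88, 4.0, 100.0, _MIN_CALL_SIZE),
        ToolProfile("codex", 0.82, 5.0, 120.0, _MIN_CALL_SIZE),
        ToolProfile("cnmops", 0.80, 1.0, 60.0, 1_000),
    ]


def noise_free_profiles(tool_ids=("exomedepth", "gcnv", "codex", "cnmops")) -> list[ToolProfile]:
    """Perfect callers: sensitivity 1, no false positives, no jitter."""
    return [ToolProfile(t, 1.0, 0.0, 0.0, 1) for t in tool_ids]


def uniform_profiles(
    n_tools: int = 4,
    sensitivity: float = 0.9,
    fp_calls_per_sample: float = 3.0,
    jitter_sd: float = 100.0,
) -> list[ToolProfile]:
    """Identical caller profiles, for controlled consensus experiments."""
    return [
        ToolProfile(f"tool{i + 1}", sensitivity, fp_calls_per_sample, jitter_sd)
        for i in range(n_tools)
    ]


@dataclass
class SimulationParams:
    """Study conditions of the synthetic cohort.

    Defaults model a 26-trio WES cohort on a compact two-chromosome
    genome: Poisson(8) germline CNVs per parent with log-uniform sizes
    between 500 bp and 6 Mb, each transmitted to the proband with
    probability 0.5, plus Poisson(1) de novo CNV per proband.
    """

    n_trios: int = 26
    chrom_model: tuple = (("1", 50_000_000), ("2", 50_000_000))
    n_true_cnv_per_person: float = 8.0
    size_range: tuple = (500, 6_000_000)
    p_del: float = 0.5
    denovo_per_proband: float = 1.0
    transmission_prob: float = 0.5
    tool_profiles: list[ToolProfile] = field(default_factory=default_tool_profiles)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (
            ("p_del", self.p_del),
            ("transmission_prob", self.transmission_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} outside [0,1]: {p}")
        if self.n_trios < 1:
            raise ValueError("need at least one trio")
        if not self.chrom_model or any(length <= 0 for _, length in self.chrom_model):
            raise ValueError(f"invalid chromosome model: {self.chrom_model}")
        lo, hi = self.size_range
        if not 0 < lo < hi:
            raise ValueError(f"invalid size range: {self.size_range}")


@dataclass
class SimulatedCohort:
    truth: TruthTable
    callsets: dict            # (sample_id, tool_id) -> ToolCallset
    manifest: list[TrioManifest]

    def callsets_for(self, sample_id: str) -> list[ToolCallset]:
        return [cs for (sid, _), cs in sorted(self.callsets.items()) if sid == sample_id]


def _draw_size(rng: np.random.Generator, size_range) -> int:
    lo, hi = size_range
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def _place_cnv(
    rng: np.random.Generator,
    params: SimulationParams,
    exclude: list[GenomicInterval],
    max_tries: int = 200,
) -> GenomicInterval | None:
    """Uniform placement avoiding a buffer around excluded intervals."""
    chroms, lengths = zip(*params.chrom_model)
    weights = np.asarray(lengths, dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        ci = rng.choice(len(chroms), p=weights)
        size = min(_draw_size(rng, params.size_range), lengths[ci] - 1)
        start = int(rng.integers(0, lengths[ci] - size))
        iv = GenomicInterval(str(chroms[ci]), start, start + size)
        clash = any(
            iv.chrom == e.chrom
            and iv.start < e.end + _TRUTH_BUFFER
            and e.start < iv.end + _TRUTH_BUFFER
            for e in exclude
        )
        if not clash:
            return iv
    return None


def _simulate_trio_truth(
    rng: np.random.Generator, params: SimulationParams, manifest: TrioManifest
) -> list[TruthCnv]:
    records: list[TruthCnv] = []
    parent_truth: dict[str, list[TruthCnv]] = {}
    for parent_id in (manifest.mother_id, manifest.father_id):
        own: list[TruthCnv] = []
        for _ in range(rng.poisson(params.n_true_cnv_per_person)):
            iv = _place_cnv(rng, params, [t.interval for t in own])
            if iv is None:
                continue
            cnv_type = DEL if rng.random() < params.p_del else DUP
            own.append(TruthCnv(iv, cnv_type, parent_id, PARENTAL_OWN))
        parent_truth[parent_id] = own
        records.extend(own)

    # transmission: an exact copy of the parental CNV, skipped when it
    # would collide with an already-inherited event
    proband: list[TruthCnv] = []
    for parent_id, origin in (
        (manifest.mother_id, MATERNAL),
        (manifest.father_id, PATERNAL),
    ):
        for t in parent_truth[parent_id]:
            if rng.random() >= params.transmission_prob:
                continue
            clash = any(
                t.interval.chrom == p.interval.chrom
                and t.interval.start < p.interval.end + _TRUTH_BUFFER
                and p.interval.start < t.interval.end + _TRUTH_BUFFER
                for p in proband
            )
            if clash:
                continue
            proband.append(TruthCnv(t.interval, t.cnv_type, manifest.proband_id, origin))

    # de novo events avoid every truth CNV of the trio so that absence
    # from the parents is unambiguous
    trio_intervals = [t.interval for t in records] + [t.interval for t in proband]
    for _ in range(rng.poisson(params.denovo_per_proband)):
        iv = _place_cnv(rng, params, trio_intervals)
        if iv is None:
            continue
        cnv_type = DEL if rng.random() < params.p_del else DUP
        proband.append(TruthCnv(iv, cnv_type, manifest.proband_id, DE_NOVO))
        trio_intervals.append(iv)

    records.extend(proband)
    return records


def _observe(
    rng: np.random.Generator,
    params: SimulationParams,
    profile: ToolProfile,
    truth: list[TruthCnv],
    sample_id: str,
) -> ToolCallset:
    chroms = {str(c): int(length) for c, length in params.chrom_model}
    calls: list[CnvCall] = []
    for t in truth:
        if rng.random() >= profile.sensitivity_for(t.interval.size()):
            continue
        start, end = t.interval.start, t.interval.end
        if profile.jitter_sd > 0:
            start += int(round(rng.normal(0, profile.jitter_sd)))
            end += int(round(rng.normal(0, profile.jitter_sd)))
        start = max(0, start)
        end = min(chroms[t.interval.chrom], end)
        if end - start < _MIN_CALL_SIZE:
            mid = max(_MIN_CALL_SIZE // 2, (start + end) // 2)
            start, end = mid - _MIN_CALL_SIZE // 2, mid + _MIN_CALL_SIZE // 2
        if end - start < profile.min_detectable_size:
            continue
        calls.append(
            CnvCall(GenomicInterval(t.interval.chrom, start, end), t.cnv_type,
                    sample_id, profile.tool_id)
        )
    names, lengths = zip(*params.chrom_model)
    weights = np.asarray(lengths, dtype=float)
    weights /= weights.sum()
    for _ in range(rng.poisson(profile.fp_calls_per_sample)):
        ci = rng.choice(len(names), p=weights)
        size = max(profile.min_detectable_size, min(_draw_size(rng, params.size_range), lengths[ci] - 1))
        start = int(rng.integers(0, lengths[ci] - size))
        cnv_type = DEL if rng.random() < params.p_del else DUP
        calls.append(
            CnvCall(GenomicInterval(str(names[ci]), start, start + size), cnv_type,
                    sample_id, profile.tool_id)
        )
    return ToolCallset(profile.tool_id, sample_id, calls)


def simulate_cohort(params: SimulationParams) -> SimulatedCohort:
    """Draw truth CNVs and per-caller observations for a trio cohort.

    Fully deterministic given ``params.seed``: the same parameters
    always yield identical truth tables, call sets and manifests.
    """
    rng = np.random.default_rng(params.seed)
    truth = TruthTable()
    callsets: dict = {}
    manifest: list[TrioManifest] = []
    for i in range(1, params.n_trios + 1):
        trio = TrioManifest(
            f"trio{i:02d}", f"trio{i:02d}.p", f"trio{i:02d}.mo", f"trio{i:02d}.fa"
        )
        manifest.append(trio)
        trio_truth = _simulate_trio_truth(rng, params, trio)
        truth.records.extend(trio_truth)
        for sample_id in (trio.proband_id, trio.mother_id, trio.father_id):
            sample_truth = [t for t in trio_truth if t.sample_id == sample_id]
            for profile in params.tool_profiles:
                callsets[(sample_id, profile.tool_id)] = _observe(
                    rng, params, profile, sample_truth, sample_id
                )
    return SimulatedCohort(truth, callsets, manifest)


@dataclass
class EvaluationReport:
    precision: float | None   # None when nothing was called
    recall: float
    f1: float | None
    n_called: int
    n_true: int
    n_matched: int


def evaluate(
    truth_calls: list, calls: list, params: ConsensusParams | None = None
) -> EvaluationReport:
    """Score a call list against truth by greedy one-to-one matching.

    Candidate pairs require the same sample and CNV type and reciprocal
    overlap >= f on both sides; pairs are consumed in order of
    decreasing overlap (the smaller of the two fractions), each call and
    each truth CNV matching at most once.
    """
    params = params or ConsensusParams()
    f = params.reciprocal_fraction
    pairs = []
    for ci, call in enumerate(calls):
        for ti, t in enumerate(truth_calls):
            if call.sample_id != t.sample_id or call.cnv_type != t.cnv_type:
                continue
            fa, fb = reciprocal_overlap(call.interval, t.interval)
            if fa >= f and fb >= f:
                pairs.append((min(fa, fb), ci, ti))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_calls: set[int] = set()
    used_truth: set[int] = set()
    for _, ci, ti in pairs:
        if ci in used_calls or ti in used_truth:
            continue
        used_calls.add(ci)
        used_truth.add(ti)
    n_matched = len(used_calls)
    precision = n_matched / len(calls) if calls else None
    recall = n_matched / len(truth_calls) if truth_calls else 0.0
    f1 = None
    if precision is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return EvaluationReport(precision, recall, f1, len(calls), len(truth_calls), n_matched)


@dataclass
class DenovoConfusion:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def specificity(self) -> float | None:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else None


def denovo_confusion(
    proband_truth: list[TruthCnv],
    inheritance: list[InheritanceCall],
    params: ConsensusParams | None = None,
) -> DenovoConfusion:
    """Confusion matrix of de novo status over proband truth CNVs.

    Each truth CNV is predicted de novo when a matching classified call
    (same type, reciprocal overlap >= f, greedy one-to-one) carries the
    de novo label; an unrecovered truth CNV is predicted non-de-novo.
    """
    params = params or ConsensusParams()
    f = params.reciprocal_fraction
    pairs = []
    for ci, call in enumerate(inheritance):
        for ti, t in enumerate(proband_truth):
            if call.cnv.sample_id != t.sample_id or call.cnv.cnv_type != t.cnv_type:
                continue
            fa, fb = reciprocal_overlap(call.cnv.interval, t.interval)
            if fa >= f and fb >= f:
                pairs.append((min(fa, fb), ci, ti))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    match_of_truth: dict[int, int] = {}
    used_calls: set[int] = set()
    for _, ci, ti in pairs:
        if ci in used_calls or ti in match_of_truth:
            continue
        used_calls.add(ci)
        match_of_truth[ti] = ci
    tp = fp = fn = tn = 0
    for ti, t in enumerate(proband_truth):
        ci = match_of_truth.get(ti)
        predicted_denovo = ci is not None and inheritance[ci].label == DE_NOVO
        truly_denovo = t.origin == DE_NOVO
        if truly_denovo and predicted_denovo:
            tp += 1
        elif truly_denovo:
            fn += 1
        elif predicted_denovo:
            fp += 1
        else:
            tn += 1
    return DenovoConfusion(tp, fp, fn, tn)


@dataclass
class PipelineResult:
    cohort: SimulatedCohort
    consensus: dict           # sample_id -> list[ConsensusCnv]
    inheritance: dict         # trio_id -> list[InheritanceCall]
    per_tool_eval: dict       # tool_id -> EvaluationReport (raw calls vs truth)
    consensus_eval: EvaluationReport
    denovo: DenovoConfusion


def run_pipeline_end_to_end(
    sim_params: SimulationParams | None = None,
    consensus_params: ConsensusParams | None = None,
) -> PipelineResult:
    """Simulate a cohort and push it through consensus, trio and evaluation.

    Individuals with fewer than two available call sets are skipped with
    a log message rather than failing, so the pipeline tolerates a
    missing caller.
    """
    sim_params = sim_params or SimulationParams()
    consensus_params = consensus_params or ConsensusParams()
    cohort = simulate_cohort(sim_params)

    consensus: dict = {}
    for trio in cohort.manifest:
        for sample_id in (trio.proband_id, trio.mother_id, trio.father_id):
            callsets = cohort.callsets_for(sample_id)
            if len(callsets) < 2:
                logger.warning(
                    "sample %s has %d caller(s); skipping consensus", sample_id, len(callsets)
                )
                consensus[sample_id] = []
                continue
            consensus[sample_id] = call_consensus(callsets, consensus_params)

    inheritance: dict = {}
    for trio in cohort.manifest:
        inheritance[trio.trio_id] = classify_trio(
            consensus[trio.proband_id],
            consensus[trio.mother_id],
            consensus[trio.father_id],
            consensus_params,
            manifest=trio,
        )

    truth_all = cohort.truth.records
    per_tool_eval = {}
    for profile in sim_params.tool_profiles:
        tool_calls = [
            c for (sid, tid), cs in cohort.callsets.items() if tid == profile.tool_id
            for c in cs
        ]
        per_tool_eval[profile.tool_id] = evaluate(truth_all, tool_calls, consensus_params)
    consensus_calls = [c for calls in consensus.values() for c in calls]
    consensus_eval = evaluate(truth_all, consensus_calls, consensus_params)

    proband_truth = [
        t for trio in cohort.manifest for t in cohort.truth.for_sample(trio.proband_id)
    ]
    all_inherit = [c for calls in inheritance.values() for c in calls]
    denovo = denovo_confusion(proband_truth, all_inherit, consensus_params)
    return PipelineResult(cohort, consensus, inheritance, per_tool_eval, consensus_eval, denovo)
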