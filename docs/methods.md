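# Methods

## The problem

Read-depth CNV calling from whole-exome sequencing is noisy: individual
callers (GATK gCNV, ExomeDepth, CODEX, cn.MOPS and kin) disagree widely in
call counts, size ranges and false-positive load, because each infers copy
number from depth fluctuations over sparse capture targets with its own
segmentation model. A standard remedy is consensus calling: treat a region
as a credible CNV only when at least two independent callers report it at
concordant coordinates. `triocnv` implements that post-processing layer for
case-parent trios — from standardised per-caller BED call sets to
high-confidence consensus CNVs, de novo/inherited labels, and prioritised
report tables — together with a simulator of caller outputs so that the
whole pipeline can be validated against known truth without any sequencing
data.

## Consensus model

All intervals are 0-based half-open, so an event's size is `end − start`.
For one sample with call sets from tools *T₁…Tₖ*:

1. **Within-tool collapse.** Overlapping or bookended same-type calls from
   one tool are union-merged. This prevents a fragmented single-caller event
   from being counted as two supporters of one region. (Whether published
   consensus workflows pre-merge within tools is typically unstated; we
   collapse, as the conservative choice for support counting.)
2. **Pairwise reciprocal intersection.** For every unordered tool pair and
   every pair of same-type calls *a, b*, let *L* be the shared length. The
   pair qualifies when *L*/|a| ≥ *f* **and** *L*/|b| ≥ *f* (reciprocal
   overlap, default *f* = 0.5, inclusive at the boundary). Each qualifying
   pair emits one fragment covering the intersection region — the region the
   callers actually agree on — not either caller's full interval.
3. **Same-type merge.** Fragments of one chromosome and CNV type merge
   transitively when they overlap or are bookended (`merge_gap = 0`;
   exposed for sensitivity analysis). The consensus interval is the union
   span; its support set is the union of the fragments' tool pairs, so
   fragments from pairs (A,B) and (B,C) yield support 3.
4. **Support filter.** Regions with fewer than `min_tools` (default 2)
   distinct supporters are dropped.

DEL and DUP never pair and never merge. Outputs are sorted by natural
chromosome order (numeric, then X, Y, M), start, end. Chromosome names are
stored verbatim (a record on an unexpected chromosome is preserved, never
"corrected"); comparisons strip a `chr` prefix case-insensitively.

The native implementation is a per-chromosome sweep; the test suite checks
it exactly against an independent reference that operates on explicit
base-coordinate sets, over hundreds of randomized multi-tool instances.

## Trio classification

A proband consensus CNV is **inherited** from a parent when that parent
carries a same-type CNV matching it at the same reciprocal threshold *f*,
and **de novo** otherwise (labels: `de_novo`, `inherited_maternal`,
`inherited_paternal`, `inherited_both`). Design choices where the procedure
was genuinely open:

- Parents are compared via their own **consensus** call sets by default;
  comparison against raw single-caller parental calls (more conservative
  for de novo claims) is available (`--parent-set raw`).
- The inheritance match reuses the consensus *f*; no separate threshold is
  introduced.
- A parental CNV of the **opposite** type never rescues a call from de novo
  status, and a sub-threshold parental overlap still yields de novo — the
  `parental_matches` field is empty exactly when the label is de novo, so
  borderline calls are auditable.

## Prioritisation gates

Annotation tables (AnnotSV-style TSV, column names configurable) carry an
ACMG class 1–5 and an Exomiser phenotype score in [0, 1]. Defaults keep
ACMG ∈ {3, 4, 5} and score ≥ 0.5 (inclusive — "at least 0.5"); kept records
are tiered `consistent` (≥ 0.5) or `highly specific` (> 0.7, strict).
Records with a missing score are excluded by the gate unless
`keep_candidates` retains them as tier `candidate`. Report rows always
recompute `size_bp = end − start`; the bundled published report tables
(24 rows) confirm this convention reproduces every printed size exactly.

## Cohort summaries

- Per-tool DEL/DUP counts and size histograms over left-closed bins
  `<1 kb, 1–100 kb, 100 kb–1 Mb, 1–10 Mb, ≥10 Mb`.
- **Overlap rate** of a tool: the percentage of its raw calls matching at
  least one same-type consensus region at *f* — i.e. how much of the
  caller's output survives into the consensus. (An alternative pairwise
  tool-vs-tool agreement mode is provided; the denominator is the tool's
  raw call count.) Percentages are rounded half-up to one decimal.
- **Deletion-vs-duplication bias**: a paired Wilcoxon signed-rank test on
  per-sample (n_DEL, n_DUP) counts. Zero differences are discarded (the
  classic convention; Pratt's method available). |d| is ranked with
  mid-ranks on ties; W is the positive-rank sum. For ≤ 25 nonzero pairs the
  two-sided p is **exact**: mid-ranks are doubled to integers and the null
  distribution of W is built by dynamic-programming convolution over sign
  assignments, so ties are handled exactly. Beyond 25 pairs a normal
  approximation is used with E[W] = Σr/2 and Var[W] = Σr²/4 (equivalent to
  the textbook n(n+1)(2n+1)/24 minus the tie correction). Tests verify the
  exact path against brute-force enumeration of all 2ⁿ sign assignments and
  against `scipy.stats.wilcoxon`.

## The simulator

The simulator emulates the pipeline's actual input boundary — caller
*output* files — not reads or depth profiles. Defaults define the study
conditions:

| parameter | default | meaning |
|---|---|---|
| `n_trios` | 26 | cohort size (proband + both parents each) |
| `chrom_model` | 2 × 50 Mb | compact synthetic genome; hg38-scale loadable from chrom.sizes |
| `n_true_cnv_per_person` | Poisson(8) | germline CNVs per parent |
| `size_range` | 500 bp – 6 Mb | log-uniform true CNV sizes |
| `p_del` | 0.5 | probability a true CNV is a deletion |
| `transmission_prob` | 0.5 | per parental CNV, probability the proband inherits it (exact coordinates) |
| `denovo_per_proband` | Poisson(1) | proband-only events |

Truth CNVs are placed uniformly with a 50 kb exclusion buffer within an
individual, and de novo events additionally avoid all parental CNVs of the
trio. The buffer keeps distinct truth events from merging into one
consensus region, which makes the no-noise limit exact (consensus ==
truth); it also means the simulator does not model genuinely overlapping or
nested CNVs, clustered hotspots, or recurrent rearrangements — pipeline
behaviour on such loci is not covered by these tests.

Each emulated caller observes the truth through a profile
(sensitivity, false-positive Poisson mean per sample, breakpoint jitter sd,
minimum detectable size). Detected calls get independent rounded-normal
jitter on both breakpoints (clamped to a 50 bp minimum size); false
positives are placed uniformly with sizes from the same log-uniform law,
**independently across callers** — the property that makes ≥2-tool
agreement informative (a correlated-artefact mode would require shared FP
seeds and is out of scope). The four default profiles reproduce the
qualitative contrasts reported for WES callers: an ExomeDepth-like profile
(sensitivity 0.95, 12 FP/sample, jitter 150 bp) calls most and agrees
least; a cn.MOPS-like profile (0.80, 1 FP/sample, jitter 60 bp, 1 kb
detection floor) calls fewest, is most specific, and contributes nothing
below 1 kb; gCNV- and CODEX-like profiles sit between. Jitter sds were
chosen small relative to the median true CNV size (~50 kb), the regime in
which reciprocal matching at f = 0.5 is reliable; no per-caller error rates
were fitted to any dataset — the profiles are plausibility settings.

What the simulator does **not** emulate: capture-target granularity (real
read-depth callers snap breakpoints to exon boundaries), GC/coverage bias,
sample-level quality variation, mosaicism, and correlated false positives
shared across callers. Passing tests therefore demonstrate the
post-processing logic is correct under the stated error model, not that any
particular caller combination achieves these precision/recall numbers on
real exomes.

## Evaluation conventions

Calls are scored against truth by greedy one-to-one matching: candidate
pairs need the same sample and type and reciprocal overlap ≥ f; pairs are
consumed in decreasing order of the smaller overlap fraction, ties broken
by position. Precision = matched/called (undefined and flagged when
nothing was called), recall = matched/true. In the simulator's regime
(buffered, well-separated truth) a call can match at most one truth event,
so greedy matching attains the maximum matching; tests assert this against
a maximum-cardinality matching oracle.

The de novo confusion matrix is computed over proband truth CNVs: a truth
event is predicted de novo when its matched, classified consensus call
carries the de novo label; an unrecovered truth event counts as predicted
non-de-novo (a miss harms sensitivity, not specificity).

One directional property deserves note: consensus **precision** dominates
every single caller under independent false positives (asserted over 100
seeded replicates), but coordinate-level consensus **recall** can exceed a
single caller's, because the merged cross-caller intersection often lies
closer to the true breakpoints than one caller's jittered interval. The
agreement constraint that does hold — every consensus-recovered truth event
is covered by raw calls from at least two distinct callers — is what the
suite asserts.

## Problem sizes and numerical choices

The default cohort (26 trios, 4 callers, ~600 truth CNVs) runs end-to-end
in ~1.5 s on one CPU; the 100-replicate consensus-dominance experiment in
~20 s. Oracle-equivalence tests use instances of ≤100 calls on small
coordinate ranges so the base-set reference stays exact and fast. All
randomness flows through `numpy.random.default_rng` seeds; identical seeds
give byte-identical outputs. Degenerate inputs are defined, not silently
handled: empty call lists error in `denovo_rate` and `overlap_rate`,
all-zero signed-rank differences return the degenerate p = 1, and a sample
with fewer than two callers is skipped with a log message rather than
crashing the cohort run.

## Known limitations

- Only the DEL/DUP dichotomy is modelled; no multi-allelic copy-number
  states, no mosaicism.
- Caller-native formats are not parsed; callers' outputs must first be
  standardised to the BED dialect (the simulator emits it directly).
- Support counting attributes a merged region to the union of its
  fragments' pair members; re-intersecting merged regions against raw calls
  could give different counts for pathological overlap chains.
- ACMG classes and Exomiser scores are consumed as given; the package never
  recomputes them.
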