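# Methods

## The problem and the model

`hfgkit` compares fusion-transcript recurrence between a disease
cohort and a control cohort to separate three origins of a fusion:

- **somatic accident** — rare in non-cancerous tissue; if one
  individual acquires a given fusion by structural variation at rate
  r, k independent acquisitions occur with probability rᵏ. With the
  literature rate r = 3.6 × 10⁻² and the recurrence threshold k = 5
  this is ≈ 6 × 10⁻⁸, and the expected number of such coincidences in
  a cohort of n individuals is n·rᵏ (≈ 1.5 × 10⁻⁵ at n = 252). Any
  fusion recurring in ≥ 5 unrelated patients is therefore effectively
  never a repeated somatic accident.
- **germline structural variation** ("hereditary fusion gene", HFG) —
  the fusion geometry implies a genomic rearrangement and the fusion
  is inherited, so it can be enriched in a disease cohort for genetic
  reasons.
- **readthrough cis-splicing** ("epigenetic fusion gene", EFG) — the
  polymerase reads through the 5′ gene's termination site into a
  same-strand downstream neighbour; no genomic change is needed, all
  genomes can in principle express it, and cohort differences reflect
  regulatory/environmental state.

### Junction classification

Classification uses only the two partner genes' annotated bodies
(chromosome, interval, strand). A junction is **EFG/readthrough** iff
the genes share chromosome and strand, the 5′ partner is
transcriptionally upstream of the 3′ partner, and the intergenic gap
is ≤ `gap_threshold` (default 200,000 bp, boundary inclusive).
Otherwise it is **GENOMIC** with mechanism: different chromosomes →
interchromosomal translocation; opposite strands → inversion; same
strand but reversed transcriptional order → duplication/order
reversal; correct order but gap > threshold → distal intrachromosomal
event. Conventions behind that rule:

- *Gap* is measured between gene bodies (outermost annotated bounds),
  not between breakpoints: the readthrough definition is a property of
  the parental genes. Overlapping bodies have gap 0 and, in correct
  order, are EFG (0 ≤ threshold). The gap is undefined across
  chromosomes.
- *Neighbouring* does not require immediate adjacency — readthrough
  transcripts spanning an intervening gene are well documented — only
  order, strand identity, and the gap bound.
- *Transcriptional order* compares gene starts along the direction of
  transcription ((start, end) lexicographically on +, mirrored on −);
  ties (identical bodies) count as correctly ordered.
- Strand-discordant pairs are never EFG regardless of gap; a
  same-strand order-reversed pair is labelled
  `duplication_or_order_reversal` without asserting mechanism truth —
  the geometry alone cannot distinguish a duplication from other
  rearrangements.
- Classification is total and deterministic; a partner gene missing
  from the annotation raises an error naming it rather than dropping
  the junction.

Coordinates are 0-based half-open internally; GTF (1-based inclusive)
is converted on read. `gap_threshold` is configuration, not a
constant.

### Recurrence and the association test

The unit of analysis is the **distinct patient**: a patient is
positive for a fusion transcript iff at least one of its runs contains
it (collapsing is idempotent under duplicated records). Fusion
*transcripts* (exact junctions) are the recurrence unit; gene pairs
aggregate transcripts into fusion *genes* for reporting.

A fusion enters testing when ≥ `min_count` (default 5) distinct
patients are positive **in either cohort** — the either-cohort rule is
required for fusions rare in cases but common in controls
(negative/protective associations) to be testable at all. The test is
the pooled two-proportion Z-test, two-sided, without continuity
correction; z² equals the uncorrected Pearson chi-square of the 2×2
table, which the tests verify against an independent chi-square
computation. When the pooled proportion is degenerate (0 or 1) there
is no variance to test against and z = 0, p = 1 by convention.
Significance is |z| ≥ z₍α/2₎ with α = 0.01 (2.576); direction is the
sign of p̂_case − p̂_control (a tie counts as non-positive). No
multiple-testing correction is applied in the reference mode; the
per-fusion p-values are reported so a user can apply one downstream.

Fold enrichment is (x₁/n₁)/(x₂/n₂); when x₂ = 0 a pseudo-count of one
positive control is substituted (18/122 vs 0/252 → 37.2-fold), and a
fusion absent from both cohorts has no fold (NaN). Frequencies are
stored exact and rounded only at report time (percentages to two
decimals, folds to one).

The **contribution split** summarizes each class's enrichment as
(mean case frequency)/(mean control frequency) over its significantly
positively associated transcripts; with HFG ratio h and EFG ratio e,
the genetic share is 100·(h/e)/(h/e + 1) and the environmental share
the complement (they sum to exactly 100). Note the arithmetic is kept
exact: a ratio chain like 8.1 : 3.3 gives 71.1 %/28.9 %, whereas
rounding the intermediate ratio to 2.48 first gives 71.3 %/28.7 % —
the implementation never rounds intermediates.

### Junction-sequence scanner

The validation algorithm is deliberately primitive: hash the junction
probes, stream the reads, call a sample positive on the first
junction-spanning read. A probe carries `flank` (default 30) bases of
transcript sequence on each side of the breakpoint. The index stores
every length-`match_len` window of a probe that spans the breakpoint
by ≥ `anchor` bases on both sides; `match_len` defaults to 2·anchor
(= 20), the minimal window carrying both anchors, so each probe
contributes exactly one key and any read that covers the junction with
both anchors is detected. The anchors are what prevent a read from
the intact 5′ (or 3′) parent gene from firing the probe. Windows
containing N are not indexed. Matching is exact — no mismatches, no
base-quality use — and the reverse complement of each read is scanned
by default. Reads shorter than `match_len` (possible only when the
user raises `match_len` above 2·anchor) are compared directly against
every breakpoint-spanning placement on each probe, still requiring
both anchors. A random 100-bp read collides with a 20-bp key with
probability ≈ 81·4⁻²⁰ < 10⁻⁹, so specificity on junction-free reads is
effectively perfect; scan results are independent of read order and
file chunking, and per-run reports collapse to patients through the
same machinery as call tables.

## The synthetic-data generator

The generator emulates the *statistical structure* the model assumes,
not RNA-seq realism: patients carry each roster fusion independently
with a cohort-specific prevalence; case patients contribute
`runs_per_case` runs (default 3) and controls one. Run-level
visibility of a positive patient is sampled at `run_detect_prob`
(default 0.7) per run, conditioned on at least one positive run, so
patient-level presence is exact — the paper-level unit is the patient,
and no planted positive can be lost to run sampling. Defaults mirror
the emulated study: 122 cases, 252 controls.

Genes are placed non-overlapping, left to right, with intergenic gaps
uniform on `gap_range` (default 20–150 kb) and random strands, on
random-base chromosomes; roster entries without explicit gene pairs
are assigned geometry compatible with their intended class, and every
planted junction is verified through the classifier before sampling.
Reads are uniform draws from gene bodies (background) plus
junction-spanning reads at `coverage_per_junction` (default 5) per
positive run, placed so each read fully contains the probe; strand is
random, substitution errors optional (default 0 — the validation
criterion is exact matching). A single master seed derives fixed
per-stage generators, so annotation, cohorts and reads are each
independently reproducible and all outputs are byte-stable.

What the generator does **not** model — expression levels, splicing
structure, sequencing quality, repeat-driven artifacts, relatedness
between patients, batch effects — bounds what passing tests show:
they validate the statistical machinery and the scanner's exactness,
not robustness to real-data noise (the known failure mode of the
scanner on real data is fusions arising from highly repetitive
sequence, which are out of scope here, as is fusion discovery itself).

## Numerical and design choices

- Critical values and p-values come from the standard normal
  (`scipy.stats.norm`); the Z statistic itself is authored here and
  cross-checked in tests against `statsmodels.proportions_ztest` and
  the chi-square identity.
- Deterministic orderings everywhere: recurrence filters sort by
  (descending count, fusion id); presence-matrix columns by
  (descending case count, fusion id), rows by patient id; association
  tables by (descending case count, fusion id). Stable sorts only.
- Isoform keys are canonical strings `5'gene--3'gene::chrom:pos::chrom:pos`;
  identical inputs always yield identical keys, and different
  breakpoints yield different isoforms. Self-fusions are rejected.
- Degenerate inputs: empty cohorts are an error at model construction;
  empty call tables produce empty (not missing) presence sets; an
  all-zero 2×2 margin yields the z = 0, p = 1 convention.
- Error model of IO: missing required columns are named; rows with
  unparseable breakpoints are logged with line numbers and dropped
  (strict mode aborts instead); unknown run IDs are listed
  exhaustively.

## Problem sizes used by tests and the acceptance script

Simulation-based checks run at the design's cohort sizes where the
quantity depends on them — type-I error (10,000 null fusions at
n = 122/252), power (1,000 replicates per direction at prevalences
0.4/0.05 and 0.05/0.4), burden and prevalence recovery — and on
smaller cohorts (15–30 patients, 16 genes, coverage 3, 50–60
background reads per run) for the read-level round trips, where
fidelity is exact by construction and independent of scale. The
classifier is compared with a brute-force rule-enumeration oracle on
1,000 random gene pairs.

## Known limitations

- Classification depends entirely on annotation quality; genes absent
  from the annotation make their junctions unclassifiable (by design,
  loudly).
- The readthrough rule is geometric; it cannot distinguish a true
  readthrough product from a genomic event that happens to mimic
  readthrough geometry, and the gap convention (gene-body to
  gene-body) shifts borderline calls relative to a
  breakpoint-distance convention.
- The Z-test is asymptotic; at the default filter (≥ 5 positives of
  122/252) the normal approximation is adequate (verified by the
  type-I simulation) but very small cohorts should use an exact test
  instead.
- The scanner is exact-match only: a single sequencing error inside
  the matched window hides a read, so sensitivity on real (noisy)
  reads depends on coverage; it also cannot resolve probes from
  repetitive sequence.
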