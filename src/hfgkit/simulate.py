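"""Synthetic study generator: annotation, cohorts, reads, with ground truth.

Emulates the structure of a two-cohort fusion-recurrence study: a case
cohort in which each patient contributes several RNA-seq runs (default
122 patients x 3 runs) and a control cohort of single-run patients
(default 252).  Each fusion in the roster is present in each patient
independently with its cohort-specific prevalence; run-level visibility
is sampled conditionally so a positive patient always shows the fusion
in at least one run.  Reads are plain genomic background plus
junction-spanning reads planted at configurable coverage for every
positive run, so every pipeline stage — classification, cohort
statistics, and the junction scanner — can be tested against known
truth without any external download.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .annotation import Annotation, GeneModel, annotation_from_genes, write_bed, write_gtf
from .cohort import CASE, CONTROL, CohortDesign, Presence
from .fusions import (
    DEFAULT_GAP_THRESHOLD,
    Category,
    FusionJunction,
    classify_fusion,
    intergenic_gap,
)
from .scanner import DEFAULT_FLANK, JunctionProbe, write_probe_fasta

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    """Raised for infeasible layouts or roster/geometry mismatches."""


@dataclass(frozen=True)
class FusionSpec:
    """One roster entry: a gene pair with per-cohort prevalence.

    ``five_prime``/``three_prime`` may be None, in which case
    :func:`resolve_roster` assigns a compatible gene pair for the
    intended category from the simulated annotation.
    """

    category: str
    case_prevalence: float
    control_prevalence: float
    five_prime: Optional[str] = None
    three_prime: Optional[str] = None

    def __post_init__(self) -> None:
        for p in (self.case_prevalence, self.control_prevalence):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"prevalence {p} outside [0, 1]")
        if self.category not in (Category.EFG.value, Category.GENOMIC.value):
            raise SimulationError(f"unknown category {self.category!r}")


#: Default roster: prevalences shaped like the headline case/control
#: recurrence pairs of a dilated-cardiomyopathy fusion study — three
#: genomic fusions (87.7/21.4 %, 22.1/1.2 %, 14.8/0 %) and three
#: readthrough fusions (99.2/52.8 %, 59.0/9.5 %, and one negatively
#: associated at 23.0/40.5 %).
DEFAULT_ROSTER: tuple[FusionSpec, ...] = (
    FusionSpec("GENOMIC", 0.877, 0.214),
    FusionSpec("GENOMIC", 0.221, 0.012),
    FusionSpec("GENOMIC", 0.148, 0.0),
    FusionSpec("EFG", 0.992, 0.528),
    FusionSpec("EFG", 0.590, 0.095),
    FusionSpec("EFG", 0.230, 0.405),
)


@dataclass(frozen=True)
class SimulationSpec:
    """Full parameterization of a synthetic study.

    Cohort defaults mirror the emulated study design: 122 case patients
    with three runs each versus 252 single-run controls.  A fixed
    ``seed`` makes every stage byte-reproducible; per-stage generators
    are derived from it at fixed offsets.
    """

    n_genes: int = 40
    n_chromosomes: int = 2
    gene_length: tuple[int, int] = (2_000, 8_000)
    gap_range: tuple[int, int] = (20_000, 150_000)
    chromosome_length: Optional[int] = None
    n_case: int = 122
    runs_per_case: int = 3
    n_control: int = 252
    roster: tuple[FusionSpec, ...] = DEFAULT_ROSTER
    gap_threshold: int = DEFAULT_GAP_THRESHOLD
    read_length: int = 100
    coverage_per_junction: int = 5
    background_reads_per_run: int = 200
    substitution_rate: float = 0.0
    probe_flank: int = DEFAULT_FLANK
    run_detect_prob: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.runs_per_case < 1:
            raise SimulationError("runs_per_case must be >= 1")
        if self.n_genes < 4:
            raise SimulationError("need at least 4 genes")
        if self.read_length < 2 * self.probe_flank:
            raise SimulationError(
                f"read_length {self.read_length} shorter than probe "
                f"({2 * self.probe_flank} bp): planted reads could not span junctions"
            )
        if not 0.0 <= self.substitution_rate < 1.0:
            raise SimulationError("substitution_rate must be in [0, 1)")
        if not 0.0 < self.run_detect_prob <= 1.0:
            raise SimulationError("run_detect_prob must be in (0, 1]")


def _rng(spec: SimulationSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng(int(spec.seed) * 16 + stage)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


# -- stage 1: annotation + genome -------------------------------------


def simulate_annotation(
    spec: SimulationSpec,
) -> tuple[dict[str, GeneModel], dict[str, str]]:
    """Place non-overlapping genes on random-sequence chromosomes.

    Genes are laid out left to right per chromosome with intergenic
    gaps drawn uniformly from ``spec.gap_range`` and random strands
    (both strands guaranteed present).  Returns ``(annotation,
    genome)`` where genome maps chromosome name to its sequence.
    Deterministic under the spec seed.

    Raises SimulationError when a fixed ``chromosome_length`` cannot
    hold the requested genes.
    """
    rng = _rng(spec, 1)
    genes: list[GeneModel] = []
    genome: dict[str, str] = {}
    per_chrom = np.array_split(np.arange(spec.n_genes), spec.n_chromosomes)
    gid = 0
    for ci, idxs in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = int(rng.integers(5_000, 10_000))
        for _ in idxs:
            length = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(
                GeneModel(
                    gene_id=f"G{gid:04d}",
                    symbol=f"GENE{gid}",
                    chrom=chrom,
                    start=pos,
                    end=pos + length,
                    strand=strand,
                )
            )
            pos += length + int(rng.integers(spec.gap_range[0], spec.gap_range[1] + 1))
        chrom_len = pos + int(rng.integers(5_000, 10_000))
        if spec.chromosome_length is not None:
            if chrom_len > spec.chromosome_length:
                raise SimulationError(
                    f"{chrom}: layout needs {chrom_len} bp but chromosome_length "
                    f"is {spec.chromosome_length}"
                )
            chrom_len = spec.chromosome_length
        genome[chrom] = _random_sequence(rng, chrom_len)
    # both strands must be represented for the roster to be resolvable
    strands = {g.strand for g in genes}
    if strands != {"+", "-"}:
        only = strands.pop()
        flip = genes[-1]
        genes[-1] = replace(flip, strand="-" if only == "+" else "+")
    return annotation_from_genes(genes), genome


# -- stage 2: roster resolution ---------------------------------------


def resolve_roster(
    spec: SimulationSpec, annotation: Annotation
) -> list[FusionSpec]:
    """Assign concrete gene pairs to roster entries lacking them.

    EFG entries get same-chromosome, same-strand, correctly ordered
    pairs with gap <= threshold; GENOMIC entries get cross-chromosome
    pairs (or inversion/distal pairs when only one chromosome exists).
    Every assignment is verified through :func:`classify_fusion`.
    """
    genes = sorted(annotation.values(), key=lambda g: (g.chrom, g.start))
    used: set[tuple[str, str]] = {
        (f.five_prime, f.three_prime)
        for f in spec.roster
        if f.five_prime and f.three_prime
    }

    def candidate_pairs(category: str):
        n = len(genes)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                a, b = genes[i], genes[j]
                pair_ids = (a.gene_id, b.gene_id)
                if pair_ids in used:
                    continue
                gap = intergenic_gap(a, b)
                if category == Category.EFG.value:
                    ok = (
                        gap is not None
                        and gap <= spec.gap_threshold
                        and a.strand == b.strand
                        and _ordered(a, b)
                    )
                else:
                    ok = gap is None or a.strand != b.strand or not _ordered(a, b) or gap > spec.gap_threshold
                if ok:
                    yield a, b

    def _ordered(a: GeneModel, b: GeneModel) -> bool:
        if a.strand == "+":
            return (a.start, a.end) <= (b.start, b.end)
        return (a.end, a.start) >= (b.end, b.start)

    resolved: list[FusionSpec] = []
    for entry in spec.roster:
        if entry.five_prime and entry.three_prime:
            resolved.append(entry)
            continue
        try:
            a, b = next(iter(candidate_pairs(entry.category)))
        except StopIteration:
            raise SimulationError(
                f"annotation offers no gene pair compatible with category "
                f"{entry.category}"
            ) from None
        used.add((a.gene_id, b.gene_id))
        resolved.append(replace(entry, five_prime=a.gene_id, three_prime=b.gene_id))
    return resolved


# -- stage 3: junctions and probes ------------------------------------


@dataclass(frozen=True)
class PlantedFusion:
    """A roster fusion with its realized junction and probe."""

    spec: FusionSpec
    junction: FusionJunction
    probe: JunctionProbe


def _transcript_flank(
    genome: dict[str, str], gene: GeneModel, pos: int, length: int, side: str
) -> str:
    """Transcript-orientation sequence flanking ``pos`` within a gene.

    ``side="5"`` returns the `length` bases transcribed immediately
    before the breakpoint; ``side="3"`` the bases immediately after.
    """
    seq = genome[gene.chrom]
    if gene.strand == "+":
        return seq[pos - length : pos] if side == "5" else seq[pos : pos + length]
    if side == "5":
        return reverse_complement(seq[pos : pos + length])
    return reverse_complement(seq[pos - length : pos])


def plant_fusions(
    spec: SimulationSpec,
    annotation: Annotation,
    genome: dict[str, str],
) -> list[PlantedFusion]:
    """Choose breakpoints and build probes for every roster fusion.

    The realized geometry of each junction is checked against its
    intended category before anything is sampled; a mismatch is an
    error.
    """
    rng = _rng(spec, 2)
    flank = spec.probe_flank
    planted = []
    for entry in resolve_roster(spec, annotation):
        five = annotation[entry.five_prime]
        three = annotation[entry.three_prime]
        margin = flank + 10
        if five.length <= 2 * margin or three.length <= 2 * margin:
            raise SimulationError(
                f"genes {five.gene_id}/{three.gene_id} too short for probe flank {flank}"
            )
        p5 = int(rng.integers(five.start + margin, five.end - margin))
        p3 = int(rng.integers(three.start + margin, three.end - margin))
        probe_seq = _transcript_flank(genome, five, p5, flank, "5") + _transcript_flank(
            genome, three, p3, flank, "3"
        )
        junction = FusionJunction(
            five_prime_gene=five.gene_id,
            three_prime_gene=three.gene_id,
            five_prime_breakpoint=(five.chrom, p5),
            three_prime_breakpoint=(three.chrom, p3),
            junction_sequence=probe_seq,
        )
        realized = classify_fusion(junction, annotation, spec.gap_threshold)
        if realized.category.value != entry.category:
            raise SimulationError(
                f"roster pair {five.gene_id}->{three.gene_id} classifies as "
                f"{realized.category.value}, not the intended {entry.category}"
            )
        probe = JunctionProbe(
            fusion_id=junction.fusion_gene_id,
            isoform_key=junction.isoform_key,
            sequence=probe_seq,
            breakpoint_offset=flank,
        )
        planted.append(PlantedFusion(entry, junction, probe))
    return planted


# -- stage 4: cohorts --------------------------------------------------


@dataclass
class SimulatedStudy:
    """Everything one synthetic study produced, with ground truth."""

    spec: SimulationSpec
    annotation: dict[str, GeneModel]
    genome: dict[str, str]
    planted: list[PlantedFusion]
    design: CohortDesign
    calls: pd.DataFrame
    presence: Presence
    truth: pd.DataFrame  # fusion_id, category, cohort, positive_patients, prevalence

    @property
    def probes(self) -> list[JunctionProbe]:
        return [p.probe for p in self.planted]


CALL_COLUMNS = [
    "run_id",
    "patient_id",
    "cohort",
    "fusion_id",
    "five_prime_gene",
    "three_prime_gene",
    "five_prime_chrom",
    "five_prime_pos",
    "three_prime_chrom",
    "three_prime_pos",
    "junction_sequence",
]


def simulate_cohorts(
    spec: SimulationSpec,
    annotation: Annotation,
    genome: dict[str, str],
    planted: Optional[list[PlantedFusion]] = None,
) -> SimulatedStudy:
    """Sample patient-level presence and run-level call tables.

    Each patient carries each roster fusion independently with the
    cohort's prevalence.  For multi-run case patients, each run of a
    positive patient shows the fusion with probability
    ``run_detect_prob``, resampled so at least one run is positive —
    patient-level presence is exact, never lost to run sampling.
    """
    if planted is None:
        planted = plant_fusions(spec, annotation, genome)
    rng = _rng(spec, 3)

    run_to_patient: dict[str, str] = {}
    patient_to_cohort: dict[str, str] = {}
    runs_of: dict[str, list[str]] = {}
    for i in range(spec.n_case):
        pid = f"DCM{i + 1:04d}"
        patient_to_cohort[pid] = CASE
        runs_of[pid] = [f"{pid}_R{r + 1}" for r in range(spec.runs_per_case)]
    for i in range(spec.n_control):
        pid = f"CTL{i + 1:04d}"
        patient_to_cohort[pid] = CONTROL
        runs_of[pid] = [f"{pid}_R1"]
    for pid, runs in runs_of.items():
        for r in runs:
            run_to_patient[r] = pid
    design = CohortDesign(run_to_patient, patient_to_cohort)

    presence: Presence = {p: set() for p in patient_to_cohort}
    rows = []
    truth_rows = []
    for pf in planted:
        fid = pf.junction.isoform_key
        counts = {CASE: 0, CONTROL: 0}
        for pid in sorted(patient_to_cohort):
            cohort = patient_to_cohort[pid]
            prev = (
                pf.spec.case_prevalence if cohort == CASE else pf.spec.control_prevalence
            )
            if rng.random() >= prev:
                continue
            presence[pid].add(fid)
            counts[cohort] += 1
            runs = runs_of[pid]
            if len(runs) == 1:
                visible = list(runs)
            else:
                mask = rng.random(len(runs)) < spec.run_detect_prob
                if not mask.any():
                    mask[rng.integers(0, len(runs))] = True
                visible = [r for r, m in zip(runs, mask) if m]
            for r in visible:
                rows.append(
                    {
                        "run_id": r,
                        "patient_id": pid,
                        "cohort": cohort,
                        "fusion_id": fid,
                        "five_prime_gene": pf.junction.five_prime_gene,
                        "three_prime_gene": pf.junction.three_prime_gene,
                        "five_prime_chrom": pf.junction.five_prime_breakpoint[0],
                        "five_prime_pos": pf.junction.five_prime_breakpoint[1],
                        "three_prime_chrom": pf.junction.three_prime_breakpoint[0],
                        "three_prime_pos": pf.junction.three_prime_breakpoint[1],
                        "junction_sequence": pf.junction.junction_sequence,
                    }
                )
        for cohort in (CASE, CONTROL):
            truth_rows.append(
                {
                    "fusion_id": fid,
                    "category": pf.spec.category,
                    "cohort": cohort,
                    "positive_patients": counts[cohort],
                    "prevalence": (
                        pf.spec.case_prevalence
                        if cohort == CASE
                        else pf.spec.control_prevalence
                    ),
                }
            )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    truth = pd.DataFrame(
        truth_rows,
        columns=["fusion_id", "category", "cohort", "positive_patients", "prevalence"],
    )
    return SimulatedStudy(
        spec=spec,
        annotation=dict(annotation),
        genome=genome,
        planted=planted,
        design=design,
        calls=calls,
        presence=presence,
        truth=truth,
    )


def simulate_study(spec: SimulationSpec) -> SimulatedStudy:
    """Run annotation + planting + cohort sampling in one call."""
    annotation, genome = simulate_annotation(spec)
    return simulate_cohorts(spec, annotation, genome)


# -- stage 5: reads ----------------------------------------------------


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = choices[int(rng.integers(0, 3))].encode()
    return arr.tobytes().decode()


def simulate_reads(
    study: SimulatedStudy,
    out_dir: str | Path,
    gzip_output: bool = True,
) -> dict[str, Path]:
    """Write per-run FASTQ files with planted junction reads + background.

    For every fusion call of a run, ``coverage_per_junction`` reads are
    emitted whose placement fully contains the junction probe (so an
    exact scanner must find them on error-free reads); strand is
    random.  Background reads are uniform draws from gene bodies of the
    reference genome and contain no junction.  Substitution errors are
    applied at the configured rate.  Returns run_id -> FASTQ path;
    byte-identical across calls with the same spec seed.
    """
    spec = study.spec
    if spec.read_length < 2 * spec.probe_flank:
        raise SimulationError("read length cannot span the junction probe")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(spec, 4)
    R = spec.read_length
    flank = spec.probe_flank
    by_key = {pf.junction.isoform_key: pf for pf in study.planted}
    genes = sorted(study.annotation.values(), key=lambda g: g.gene_id)
    calls_by_run = dict(tuple(study.calls.groupby("run_id", sort=True)))

    paths: dict[str, Path] = {}
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    for run_id in sorted(study.design.run_to_patient):
        path = out_dir / f"{run_id}{suffix}"
        opener = gzip.open if gzip_output else open
        with opener(path, "wt") as fh:
            read_no = 0

            def emit(seq: str) -> None:
                nonlocal read_no
                read_no += 1
                seq = _apply_errors(rng, seq, spec.substitution_rate)
                fh.write(f"@{run_id}.{read_no}\n{seq}\n+\n{'I' * len(seq)}\n")

            sub = calls_by_run.get(run_id)
            if sub is not None:
                for fid in sub["fusion_id"]:
                    pf = by_key[str(fid)]
                    five = study.annotation[pf.junction.five_prime_gene]
                    three = study.annotation[pf.junction.three_prime_gene]
                    ctx5 = _transcript_flank(
                        study.genome, five, pf.junction.five_prime_breakpoint[1], R, "5"
                    )
                    ctx3 = _transcript_flank(
                        study.genome, three, pf.junction.three_prime_breakpoint[1], R, "3"
                    )
                    context = ctx5 + ctx3
                    junction_at = len(ctx5)
                    lo = junction_at - R + flank
                    hi = junction_at - flank
                    for _ in range(spec.coverage_per_junction):
                        s = int(rng.integers(lo, hi + 1))
                        read = context[s : s + R]
                        if rng.random() < 0.5:
                            read = reverse_complement(read)
                        emit(read)
            for _ in range(spec.background_reads_per_run):
                g = genes[int(rng.integers(0, len(genes)))]
                if g.length <= R:
                    start, stop = g.start, g.start + min(R, g.length)
                else:
                    start = int(rng.integers(g.start, g.end - R))
                    stop = start + R
                read = study.genome[g.chrom][start:stop]
                if rng.random() < 0.5:
                    read = reverse_complement(read)
                emit(read)
        paths[run_id] = path
    return paths


# -- file export -------------------------------------------------------


def write_study(
    study: SimulatedStudy,
    out_dir: str | Path,
    with_reads: bool = True,
    gzip_reads: bool = True,
) -> dict[str, Path]:
    """Write annotation (GTF+BED), genome FASTA, tables, probes and reads."""
    from .io import write_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["gtf"] = out_dir / "annotation.gtf"
    write_gtf(study.annotation, paths["gtf"])
    paths["bed"] = out_dir / "annotation.bed"
    write_bed(study.annotation, paths["bed"])

    paths["genome"] = out_dir / "genome.fa"
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(study.genome):
            fh.write(f">{chrom}\n")
            seq = study.genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    paths["calls"] = out_dir / "calls.tsv"
    write_table(study.calls, paths["calls"])
    paths["design"] = out_dir / "design.tsv"
    write_table(study.design.to_dataframe(), paths["design"])
    paths["truth"] = out_dir / "truth.tsv"
    write_table(study.truth, paths["truth"])
    paths["probes"] = out_dir / "probes.fa"
    write_probe_fasta(study.probes, paths["probes"])

    if with_reads:
        reads_dir = out_dir / "reads"
        for run, p in simulate_reads(study, reads_dir, gzip_output=gzip_reads).items():
            paths[f"fastq:{run}"] = p
    return paths
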