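"""Fusion-junction domain types and the EFG/genomic classification rules.

A fusion transcript joins a 5' partner gene to a 3' partner gene at a
specific pair of breakpoints; one gene pair ("fusion gene") can express
many such junction isoforms.  Each junction is classified as either an
epigenetic fusion gene (EFG) candidate — a readthrough product of
cis-splicing across two same-strand neighbouring genes — or as the
product of a genomic rearrangement (hereditary fusion gene candidate),
with a mechanism subtype.

The readthrough rule: the two genes lie on the same chromosome and the
same strand, the 5' partner is transcriptionally upstream of the 3'
partner, and the intergenic gap between the gene bodies is at most
``gap_threshold`` (default 200,000 bp).  Anything else implies a genomic
rearrangement: different chromosomes mean a translocation; opposite
strands on one chromosome mean an inversion; same strand but reversed
transcriptional order suggests a duplication or order reversal; and a
correctly ordered same-strand pair separated by more than the threshold
is a distal intrachromosomal event (insertion/deletion/intra-chromosomal
translocation).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .annotation import Annotation, GeneModel

#: Default intergenic-gap threshold (bp) separating readthrough from
#: distal genomic events.
DEFAULT_GAP_THRESHOLD = 200_000


class Category(str, enum.Enum):
    """Top-level fusion class: readthrough (EFG) vs genomic rearrangement."""

    EFG = "EFG"
    GENOMIC = "GENOMIC"


class Mechanism(str, enum.Enum):
    READTHROUGH = "readthrough"
    INTERCHROMOSOMAL_TRANSLOCATION = "interchromosomal_translocation"
    INVERSION = "inversion"
    DUPLICATION_OR_ORDER_REVERSAL = "duplication_or_order_reversal"
    DISTAL_INTRACHROMOSOMAL = "distal_intrachromosomal"


class UnresolvableGeneError(KeyError):
    """A fusion partner gene is missing from the annotation."""

    def __init__(self, gene_id: str):
        self.gene_id = gene_id
        super().__init__(f"gene {gene_id!r} not found in annotation")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


@dataclass(frozen=True)
class FusionClass:
    """Classification verdict for one junction.

    ``gap_bp`` is defined (non-None) exactly when both partners share a
    chromosome; ``category`` is EFG iff ``mechanism`` is readthrough.
    """

    category: Category
    mechanism: Mechanism
    gap_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.category is Category.EFG) != (self.mechanism is Mechanism.READTHROUGH):
            raise ValueError("category EFG <=> mechanism readthrough")


@dataclass(frozen=True)
class FusionJunction:
    """One fusion isoform: a gene pair plus its exact breakpoints.

    ``five_prime_breakpoint`` / ``three_prime_breakpoint`` are
    ``(chrom, position)`` pairs (0-based).  ``isoform_key`` is a
    deterministic canonical identifier: junctions with the same gene
    pair but different breakpoints are distinct isoforms.
    """

    five_prime_gene: str
    three_prime_gene: str
    five_prime_breakpoint: tuple[str, int]
    three_prime_breakpoint: tuple[str, int]
    junction_sequence: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.five_prime_gene == self.three_prime_gene:
            raise ValueError(
                f"self-fusion rejected: 5' and 3' partner are both {self.five_prime_gene!r}"
            )

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.five_prime_gene, self.three_prime_gene)

    @property
    def fusion_gene_id(self) -> str:
        """Gene-pair level identifier (aggregates all isoforms)."""
        return f"{self.five_prime_gene}--{self.three_prime_gene}"

    @property
    def isoform_key(self) -> str:
        c5, p5 = self.five_prime_breakpoint
        c3, p3 = self.three_prime_breakpoint
        return f"{self.fusion_gene_id}::{c5}:{p5}::{c3}:{p3}"


def intergenic_gap(a: GeneModel, b: GeneModel) -> Optional[int]:
    """Bases strictly between two gene bodies; 0 if they overlap.

    Returns None ("undefined") when the genes sit on different
    chromosomes.  Total: never raises.
    """
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


def _in_transcriptional_order(five: GeneModel, three: GeneModel) -> bool:
    """Is the 5' gene transcriptionally upstream of (or level with) the 3' gene?

    On the + strand upstream means smaller coordinates; on the - strand
    the axis is mirrored.  Overlapping or coincident bodies count as
    correctly ordered (the gap rule then sees gap 0).
    """
    if five.strand == "+":
        return (five.start, five.end) <= (three.start, three.end)
    return (five.end, five.start) >= (three.end, three.start)


def classify_fusion(
    junction: FusionJunction,
    annotation: Annotation,
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
) -> FusionClass:
    """Classify one junction as EFG (readthrough) or GENOMIC with mechanism.

    Raises
    ------
    UnresolvableGeneError
        If either partner gene is absent from the annotation; partners
        are never silently dropped.
    """
    try:
        five = annotation[junction.five_prime_gene]
    except KeyError:
        raise UnresolvableGeneError(junction.five_prime_gene) from None
    try:
        three = annotation[junction.three_prime_gene]
    except KeyError:
        raise UnresolvableGeneError(junction.three_prime_gene) from None

    gap = intergenic_gap(five, three)
    if gap is None:
        return FusionClass(Category.GENOMIC, Mechanism.INTERCHROMOSOMAL_TRANSLOCATION, None)
    if five.strand != three.strand:
        return FusionClass(Category.GENOMIC, Mechanism.INVERSION, gap)
    if not _in_transcriptional_order(five, three):
        return FusionClass(Category.GENOMIC, Mechanism.DUPLICATION_OR_ORDER_REVERSAL, gap)
    if gap <= gap_threshold:
        return FusionClass(Category.EFG, Mechanism.READTHROUGH, gap)
    return FusionClass(Category.GENOMIC, Mechanism.DISTAL_INTRACHROMOSOMAL, gap)


def aggregate_to_fusion_genes(
    junctions: Iterable[FusionJunction],
) -> dict[tuple[str, str], set[str]]:
    """Group junction isoforms by (5' gene, 3' gene) pair.

    The transcript level ("fusion transcripts") collapses to the gene
    level ("fusion genes"): each pair maps to the set of its distinct
    isoform keys, so the total isoform count is preserved.
    """
    out: dict[tuple[str, str], set[str]] = {}
    for j in junctions:
        out.setdefault(j.gene_pair, set()).add(j.isoform_key)
    return out
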