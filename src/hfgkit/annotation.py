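"""Gene annotation: the minimal gene model and GTF/BED readers and writers.

Classification of fusion junctions only needs, for each gene, its
chromosome, gene-body interval and strand.  Coordinates are held 0-based,
half-open throughout the package; GTF input (1-based, inclusive) is
converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pyranges


class AnnotationError(ValueError):
    """Raised when an annotation file or record is invalid."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: the unit of fusion-partner geometry.

    Attributes
    ----------
    gene_id : str
        Stable identifier used to resolve fusion partners.
    symbol : str
        Display name (may equal ``gene_id``).
    chrom : str
        Chromosome name.
    start, end : int
        Gene-body bounds, 0-based half-open, ``start < end``.
    strand : str
        ``"+"`` or ``"-"``.
    """

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def tss(self) -> int:
        """Transcription start coordinate (0-based) of the gene body."""
        return self.start if self.strand == "+" else self.end - 1


Annotation = Mapping[str, GeneModel]
"""An annotation is simply a mapping ``gene_id -> GeneModel``."""


def annotation_from_genes(genes: Iterable[GeneModel]) -> dict[str, GeneModel]:
    """Build the gene_id -> GeneModel mapping, rejecting duplicate ids."""
    out: dict[str, GeneModel] = {}
    for g in genes:
        if g.gene_id in out:
            raise AnnotationError(f"duplicate gene_id {g.gene_id!r} in annotation")
        out[g.gene_id] = g
    return out


def read_gtf(path: str | Path) -> dict[str, GeneModel]:
    """Read gene features from a GTF file.

    Only rows with feature type ``gene`` are used; 1-based inclusive GTF
    coordinates are converted to the internal 0-based half-open convention.
    A missing strand (``.``) is an error: strand drives classification.
    """
    gr = pyranges.read_gtf(str(path))
    df = gr.df
    if df.empty:
        raise AnnotationError(f"{path}: no features found")
    df = df[df["Feature"] == "gene"]
    if df.empty:
        raise AnnotationError(f"{path}: no 'gene' features found")
    if "gene_id" not in df.columns:
        raise AnnotationError(f"{path}: gene features lack gene_id attributes")
    genes = []
    for row in df.itertuples(index=False):
        strand = str(row.Strand)
        if strand not in ("+", "-"):
            raise AnnotationError(
                f"{path}: gene {row.gene_id} has no usable strand ({strand!r})"
            )
        symbol = getattr(row, "gene_name", None) or row.gene_id
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                symbol=str(symbol),
                chrom=str(row.Chromosome),
                start=int(row.Start),
                end=int(row.End),
                strand=strand,
            )
        )
    return annotation_from_genes(genes)


_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> dict[str, GeneModel]:
    """Read a 6-column BED file (already 0-based half-open).

    The ``name`` column supplies both gene_id and symbol; the strand
    column is mandatory.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str
    )
    if df.shape[1] < 6:
        raise AnnotationError(
            f"{path}: BED must have >= 6 columns (strand is mandatory), got {df.shape[1]}"
        )
    df = df.iloc[:, :6]
    df.columns = _BED_COLUMNS
    genes = []
    for row in df.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise AnnotationError(f"{path}: gene {row.name} has invalid strand {row.strand!r}")
        genes.append(
            GeneModel(
                gene_id=str(row.name),
                symbol=str(row.name),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
            )
        )
    return annotation_from_genes(genes)


def read_annotation(path: str | Path) -> dict[str, GeneModel]:
    """Dispatch on file extension: ``.gtf``/``.gtf.gz`` vs ``.bed``."""
    name = str(path).lower()
    if name.endswith((".gtf", ".gtf.gz")):
        return read_gtf(path)
    if name.endswith((".bed", ".bed.gz")):
        return read_bed(path)
    raise AnnotationError(f"cannot infer annotation format from {path!r} (use .gtf or .bed)")


def write_gtf(annotation: Annotation, path: str | Path, source: str = "hfgkit") -> None:
    """Write gene features as GTF (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in sorted(annotation.values(), key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_bed(annotation: Annotation, path: str | Path) -> None:
    """Write genes as 6-column BED (0-based half-open, as stored)."""
    with open(path, "w") as fh:
        for g in sorted(annotation.values(), key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
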