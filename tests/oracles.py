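"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written as a flat rule-by-rule enumeration, sharing no
code with the package's classifier.
"""

from hfgkit import GeneModel


def classify_oracle(five: GeneModel, three: GeneModel, gap_threshold: int = 200_000):
    """Return (category, mechanism, gap_bp) by explicit case enumeration."""
    if five.chrom != three.chrom:
        return ("GENOMIC", "interchromosomal_translocation", None)

    # bases strictly between the bodies; overlap clamps to zero
    gap = max(five.start, three.start) - min(five.end, three.end)
    if gap < 0:
        gap = 0

    if five.strand != three.strand:
        return ("GENOMIC", "inversion", gap)

    if five.strand == "+":
        ordered = five.start < three.start or (
            five.start == three.start and five.end <= three.end
        )
    else:
        ordered = five.end > three.end or (
            five.end == three.end and five.start >= three.start
        )
    if not ordered:
        return ("GENOMIC", "duplication_or_order_reversal", gap)
    if gap > gap_threshold:
        return ("GENOMIC", "distal_intrachromosomal", gap)
    return ("EFG", "readthrough", gap)


def random_gene_pair(rng, n_chrom=2, span=1_000_000):
    """Draw two non-identical random genes for oracle comparisons."""
    genes = []
    for gid in ("X1", "X2"):
        start = int(rng.integers(0, span))
        length = int(rng.integers(100, 50_000))
        genes.append(
            GeneModel(
                gene_id=gid,
                symbol=gid,
                chrom=f"chr{int(rng.integers(1, n_chrom + 1))}",
                start=start,
                end=start + length,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    return genes[0], genes[1]
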