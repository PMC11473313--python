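"""Junction-sequence read scanner: hash-table screening of RNA-seq reads.

The validation procedure for a fusion call set is deliberately simple:
build a hash table of fusion-junction probe sequences, stream every
sequencing read of a sample through it, and call the sample positive
for a fusion when at least one read carries a junction-spanning match.

A probe holds L bases of transcript sequence on each side of the
breakpoint (default L = 30).  The index stores every length-`match_len`
window of each probe that straddles the breakpoint by at least `anchor`
bases on both sides (default anchor = 10, match_len = 2 * anchor), so a
read matching the 5' gene alone can never fire a probe.  Matching is
exact — no mismatches, no quality filtering — and by default both the
read and its reverse complement are scanned.
"""

from __future__ import annotations

import gzip
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import pandas as pd
from Bio.Seq import reverse_complement
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .cohort import CohortDesign, Presence, collapse_runs_to_patients

DEFAULT_ANCHOR = 10
DEFAULT_FLANK = 30

_VALID_BASES = frozenset("ACGTN")


class ProbeError(ValueError):
    """Raised for malformed probes or probe/index mismatches."""


class FastqFormatError(ValueError):
    """Malformed FASTQ input, annotated with the failing record number."""


@dataclass(frozen=True)
class JunctionProbe:
    """A junction-spanning probe: `flank` bases each side of the breakpoint.

    ``breakpoint_offset`` is the 0-based position of the first base
    after the junction, i.e. the length of the 5' half.
    """

    fusion_id: str
    isoform_key: str
    sequence: str
    breakpoint_offset: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq or set(seq) - _VALID_BASES:
            raise ProbeError(
                f"probe {self.isoform_key}: sequence must be non-empty A/C/G/T/N"
            )
        if not 0 < self.breakpoint_offset < len(seq):
            raise ProbeError(
                f"probe {self.isoform_key}: breakpoint offset {self.breakpoint_offset} "
                f"outside sequence of length {len(seq)}"
            )


class JunctionIndex:
    """Exact-lookup index over breakpoint-spanning probe windows."""

    def __init__(
        self,
        probes: list[JunctionProbe],
        match_len: int,
        anchor: int,
    ) -> None:
        self.probes = probes
        self.match_len = match_len
        self.anchor = anchor
        # window sequence -> set of probe indices (multi-hits kept)
        self.windows: dict[str, set[int]] = defaultdict(set)
        for idx, probe in enumerate(probes):
            seq, bp = probe.sequence, probe.breakpoint_offset
            if len(seq) < match_len:
                raise ProbeError(
                    f"probe {probe.isoform_key} (length {len(seq)}) is shorter "
                    f"than match_len {match_len}"
                )
            lo = max(0, bp + anchor - match_len)
            hi = min(len(seq) - match_len, bp - anchor)
            for s in range(lo, hi + 1):
                window = seq[s : s + match_len]
                if "N" in window:
                    continue
                self.windows[window].add(idx)
        self.windows = dict(self.windows)

    def lookup_sequence(self, seq: str) -> set[int]:
        """Probe indices supported by any spanning window within `seq`."""
        hits: set[int] = set()
        n, m = len(seq), self.match_len
        if n >= m:
            for s in range(n - m + 1):
                found = self.windows.get(seq[s : s + m])
                if found:
                    hits |= found
        elif n >= 2 * self.anchor:
            # Read shorter than match_len: compare it directly against
            # every breakpoint-spanning placement on every probe, still
            # requiring both anchors.
            for idx, probe in enumerate(self.probes):
                if idx in hits:
                    continue
                pseq, bp = probe.sequence, probe.breakpoint_offset
                lo = max(0, bp + self.anchor - n)
                hi = min(len(pseq) - n, bp - self.anchor)
                for s in range(lo, hi + 1):
                    if pseq[s : s + n] == seq:
                        hits.add(idx)
                        break
        return hits


def build_junction_index(
    probes: Iterable[JunctionProbe],
    match_len: Optional[int] = None,
    anchor: int = DEFAULT_ANCHOR,
) -> JunctionIndex:
    """Build the hash table of breakpoint-spanning probe windows.

    ``match_len`` defaults to ``2 * anchor``, the minimal window that
    still carries both anchors; with the defaults each probe
    contributes exactly one 20-mer key.  Windows containing N are
    excluded.  Raises ProbeError, naming the probe, if any probe is
    shorter than ``match_len``.
    """
    probes = list(probes)
    if match_len is None:
        match_len = 2 * anchor
    if match_len < 2 * anchor:
        raise ProbeError(
            f"match_len {match_len} cannot hold both {anchor}-base anchors"
        )
    return JunctionIndex(probes, match_len=match_len, anchor=anchor)


@dataclass
class ScanReport:
    """Per-sample scan outcome.

    ``isoform_read_counts`` counts supporting reads per isoform probe;
    ``fusion_read_counts`` aggregates them per fusion gene.  A fusion
    is positive when at least one read supports any of its probes.
    """

    sample_id: str
    isoform_read_counts: dict[str, int] = field(default_factory=dict)
    fusion_read_counts: dict[str, int] = field(default_factory=dict)
    fusion_isoform_counts: dict[str, int] = field(default_factory=dict)
    n_reads: int = 0

    def positive_fusions(self) -> set[str]:
        return {f for f, c in self.fusion_read_counts.items() if c >= 1}

    def positive_isoforms(self) -> set[str]:
        return {k for k, c in self.isoform_read_counts.items() if c >= 1}

    def is_positive(self, fusion_id: str) -> bool:
        return self.fusion_read_counts.get(fusion_id, 0) >= 1

    def to_dataframe(self, index: Optional[JunctionIndex] = None) -> pd.DataFrame:
        """Per-isoform table: fusion_id, isoform_key, read_count, positive."""
        rows = []
        known: dict[str, str] = {}
        if index is not None:
            known = {p.isoform_key: p.fusion_id for p in index.probes}
        keys = sorted(set(self.isoform_read_counts) | set(known))
        for k in keys:
            c = self.isoform_read_counts.get(k, 0)
            rows.append(
                {
                    "sample_id": self.sample_id,
                    "fusion_id": known.get(k, k.split("::")[0]),
                    "isoform_key": k,
                    "read_count": c,
                    "positive": c >= 1,
                }
            )
        return pd.DataFrame(
            rows, columns=["sample_id", "fusion_id", "isoform_key", "read_count", "positive"]
        )


ReadSource = Union[str, Path, Iterable[tuple[str, str]]]


def _iter_reads(source: ReadSource) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a FASTQ path (.gz ok) or an iterable."""
    if isinstance(source, (str, Path)):
        opener = gzip.open if str(source).endswith(".gz") else open
        with opener(source, "rt") as handle:
            record_no = 0
            try:
                for name, seq, _qual in FastqGeneralIterator(handle):
                    record_no += 1
                    yield name, seq
            except ValueError as exc:
                raise FastqFormatError(
                    f"{source}: malformed FASTQ at record {record_no + 1}: {exc}"
                ) from exc
    else:
        yield from source


def scan_reads(
    reads: ReadSource,
    index: JunctionIndex,
    sample_id: str = "sample",
    with_reverse_complement: bool = True,
) -> ScanReport:
    """Stream reads through the junction index and count supporting reads.

    A read supports a probe iff it contains an indexed
    breakpoint-spanning window of that probe, on the forward strand or
    (by default) on the reverse complement.  Each read contributes at
    most one count per isoform.  Memory use is independent of input
    size; results do not depend on read order.
    """
    report = ScanReport(sample_id=sample_id)
    iso_counts: dict[str, int] = defaultdict(int)
    for _name, seq in _iter_reads(reads):
        seq = seq.upper()
        report.n_reads += 1
        hits = index.lookup_sequence(seq)
        if with_reverse_complement:
            hits |= index.lookup_sequence(reverse_complement(seq))
        for idx in hits:
            iso_counts[index.probes[idx].isoform_key] += 1
    report.isoform_read_counts = dict(iso_counts)
    fusion_counts: dict[str, int] = defaultdict(int)
    fusion_isoforms: dict[str, set[str]] = defaultdict(set)
    by_key = {p.isoform_key: p.fusion_id for p in index.probes}
    for key, c in iso_counts.items():
        fusion_counts[by_key[key]] += c
        fusion_isoforms[by_key[key]].add(key)
    report.fusion_read_counts = dict(fusion_counts)
    report.fusion_isoform_counts = {f: len(s) for f, s in fusion_isoforms.items()}
    return report


def scan_sample(
    fastq_paths: Iterable[str | Path],
    index: JunctionIndex,
    sample_id: str = "sample",
    with_reverse_complement: bool = True,
) -> ScanReport:
    """Scan one sample spread over several FASTQ files into one report."""
    merged = ScanReport(sample_id=sample_id)
    iso: dict[str, int] = defaultdict(int)
    for path in fastq_paths:
        part = scan_reads(path, index, sample_id, with_reverse_complement)
        merged.n_reads += part.n_reads
        for k, c in part.isoform_read_counts.items():
            iso[k] += c
    merged.isoform_read_counts = dict(iso)
    by_key = {p.isoform_key: p.fusion_id for p in index.probes}
    fusion_counts: dict[str, int] = defaultdict(int)
    fusion_isoforms: dict[str, set[str]] = defaultdict(set)
    for key, c in iso.items():
        fusion_counts[by_key[key]] += c
        fusion_isoforms[by_key[key]].add(key)
    merged.fusion_read_counts = dict(fusion_counts)
    merged.fusion_isoform_counts = {f: len(s) for f, s in fusion_isoforms.items()}
    return merged


def summarize_scan(
    reports: Iterable[ScanReport],
    design: CohortDesign,
    unit: str = "isoform",
) -> Presence:
    """Collapse per-run scan reports to per-patient presence sets.

    Each report's sample_id must be a run ID of the design; presence is
    at isoform level (``unit="isoform"``, the recurrence unit) or at
    fusion-gene level (``unit="fusion"``).  The result feeds
    ``recurrence_table`` unchanged.
    """
    if unit not in ("isoform", "fusion"):
        raise ValueError(f"unit must be 'isoform' or 'fusion', got {unit!r}")
    rows = []
    for rep in reports:
        ids = rep.positive_isoforms() if unit == "isoform" else rep.positive_fusions()
        for fid in ids:
            rows.append({"run_id": rep.sample_id, "fusion_id": fid})
    calls = pd.DataFrame(rows, columns=["run_id", "fusion_id"])
    return collapse_runs_to_patients(calls, design)


# -- probe IO ----------------------------------------------------------


def write_probe_fasta(probes: Iterable[JunctionProbe], path: str | Path) -> None:
    """Write probes as FASTA with ``fusion_id|isoform_key|offset`` headers."""
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f">{p.fusion_id}|{p.isoform_key}|{p.breakpoint_offset}\n")
            fh.write(p.sequence + "\n")


def read_probe_fasta(path: str | Path) -> list[JunctionProbe]:
    """Read probes written by :func:`write_probe_fasta`."""
    probes = []
    header: Optional[str] = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        parts = header.split("|")
        if len(parts) != 3:
            raise ProbeError(
                f"{path}: probe header {header!r} is not fusion_id|isoform_key|offset"
            )
        probes.append(
            JunctionProbe(
                fusion_id=parts[0],
                isoform_key=parts[1],
                sequence="".join(chunks),
                breakpoint_offset=int(parts[2]),
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            else:
                chunks.append(line)
        flush()
    return probes
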