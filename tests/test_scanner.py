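"""Junction scanner: index construction, read screening, round trips."""

import gzip

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from hfgkit import (
    FusionAssociationModel,
    JunctionProbe,
    build_junction_index,
    read_probe_fasta,
    recurrence_table,
    scan_reads,
    scan_sample,
    simulate_reads,
    summarize_scan,
    write_probe_fasta,
)
from hfgkit.scanner import FastqFormatError, ProbeError

RNG = np.random.default_rng(42)
BASES = np.array(list("ACGT"))


def random_seq(n, rng=RNG):
    return "".join(BASES[rng.integers(0, 4, size=n)])


@pytest.fixture
def probe():
    return JunctionProbe("GA--GB", "GA--GB::chr1:5::chr1:9", random_seq(60, np.random.default_rng(1)), 30)


class TestJunctionProbe:
    def test_invalid_sequence_rejected(self):
        with pytest.raises(ProbeError):
            JunctionProbe("f", "k", "ACGTX", 2)

    def test_offset_must_be_internal(self):
        with pytest.raises(ProbeError):
            JunctionProbe("f", "k", "ACGT", 4)


class TestBuildIndex:
    def test_full_length_window_single_key(self, probe):
        index = build_junction_index([probe], match_len=60)
        assert len(index.windows) == 1
        assert index.lookup_sequence(probe.sequence) == {0}

    def test_default_window_spans_breakpoint_with_anchors(self, probe):
        index = build_junction_index([probe])  # anchor 10, match_len 20
        assert set(index.windows) == {probe.sequence[20:40]}

    def test_all_indexed_windows_span_breakpoint(self, probe):
        index = build_junction_index([probe], match_len=30)
        for window in index.windows:
            pos = probe.sequence.find(window)
            assert pos <= probe.breakpoint_offset - index.anchor
            assert pos + 30 >= probe.breakpoint_offset + index.anchor

    def test_probe_shorter_than_match_len_named_in_error(self, probe):
        with pytest.raises(ProbeError, match=probe.isoform_key):
            build_junction_index([probe], match_len=61)

    def test_windows_with_N_excluded(self):
        seq = random_seq(29, np.random.default_rng(2)) + "N" + random_seq(30, np.random.default_rng(3))
        p = JunctionProbe("f", "f::1", seq, 30)
        index = build_junction_index([p])  # the only spanning 20-mer holds the N
        assert index.windows == {}

    def test_shared_five_prime_flank_gives_no_shared_spanning_keys(self):
        """Probes differing only 3' of the junction never collide.

        Verified against brute-force window enumeration.
        """
        rng = np.random.default_rng(4)
        shared5 = random_seq(30, rng)
        pa = JunctionProbe("f", "f::a", shared5 + random_seq(30, rng), 30)
        pb = JunctionProbe("f", "f::b", shared5 + random_seq(30, rng), 30)
        index = build_junction_index([pa, pb], match_len=20, anchor=10)
        shared = {w for w, hits in index.windows.items() if len(hits) > 1}
        # brute force: enumerate every spanning 20-mer of each probe
        def spanning(p):
            return {
                p.sequence[s : s + 20]
                for s in range(41)
                if s <= 20 and s + 20 >= 40
            }
        assert spanning(pa) & spanning(pb) == set()
        assert shared == set()


class TestScanReads:
    def test_planted_probe_found_at_offset(self, probe):
        index = build_junction_index([probe])
        read = random_seq(7) + probe.sequence + random_seq(13)
        report = scan_reads([("r1", read)], index, "s1")
        assert report.isoform_read_counts == {probe.isoform_key: 1}
        assert report.is_positive("GA--GB")

    def test_reverse_complement_flag(self, probe):
        index = build_junction_index([probe])
        read = reverse_complement(random_seq(7) + probe.sequence + random_seq(13))
        on = scan_reads([("r1", read)], index, "s1", with_reverse_complement=True)
        off = scan_reads([("r1", read)], index, "s1", with_reverse_complement=False)
        assert on.isoform_read_counts == {probe.isoform_key: 1}
        assert off.isoform_read_counts == {}

    def test_read_counted_once_despite_multiple_windows(self, probe):
        index = build_junction_index([probe], match_len=22)
        report = scan_reads([("r1", probe.sequence)], index, "s1")
        assert report.isoform_read_counts[probe.isoform_key] == 1

    def test_no_hits_on_random_reads(self, probe):
        index = build_junction_index([probe], anchor=15, match_len=30)
        rng = np.random.default_rng(5)
        reads = [("r%d" % i, random_seq(100, rng)) for i in range(3000)]
        report = scan_reads(reads, index, "s1")
        assert report.isoform_read_counts == {}
        assert report.n_reads == 3000

    def test_short_read_fallback_requires_both_anchors(self, probe):
        index = build_junction_index([probe], match_len=60)
        spanning = probe.sequence[15:55]  # 40 bp: 15 before + 25 after the junction
        not_spanning = probe.sequence[32:60]  # entirely 3' of the junction
        assert scan_reads([("a", spanning)], index).isoform_read_counts
        assert not scan_reads([("b", not_spanning)], index).isoform_read_counts

    def test_order_and_chunking_invariance(self, probe):
        index = build_junction_index([probe])
        rng = np.random.default_rng(6)
        reads = [("r%d" % i, random_seq(80, rng)) for i in range(50)]
        reads += [("hit", random_seq(10, rng) + probe.sequence + random_seq(10, rng))]
        fwd = scan_reads(list(reads), index, "s")
        rev = scan_reads(list(reversed(reads)), index, "s")
        assert fwd.isoform_read_counts == rev.isoform_read_counts

    def test_malformed_fastq_reports_record_number(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\nBROKEN\n")
        index = build_junction_index(
            [JunctionProbe("f", "f::1", random_seq(60, np.random.default_rng(8)), 30)]
        )
        with pytest.raises(FastqFormatError, match="record 2"):
            scan_reads(str(path), index, "s")

    def test_gzip_and_multi_file_sample(self, tmp_path, probe):
        index = build_junction_index([probe])
        read = random_seq(5) + probe.sequence + random_seq(5)
        p1 = tmp_path / "a.fastq.gz"
        with gzip.open(p1, "wt") as fh:
            fh.write(f"@r1\n{read}\n+\n{'I' * len(read)}\n")
        p2 = tmp_path / "b.fastq"
        p2.write_text(f"@r2\n{read}\n+\n{'I' * len(read)}\n")
        report = scan_sample([p1, p2], index, "s")
        assert report.isoform_read_counts[probe.isoform_key] == 2
        assert report.n_reads == 2


class TestProbeFastaRoundTrip:
    def test_write_then_read_identity(self, tmp_path, probe):
        path = tmp_path / "probes.fa"
        write_probe_fasta([probe], path)
        back = read_probe_fasta(path)
        assert back == [probe]


@pytest.fixture(scope="module")
def scanned(small_study, tmp_path_factory):
    out = tmp_path_factory.mktemp("reads")
    paths = simulate_reads(small_study, out)
    index = build_junction_index(small_study.probes)
    return {run: scan_reads(path, index, sample_id=run) for run, path in paths.items()}


class TestRoundTripWithSimulator:
    def test_sensitivity_and_specificity_per_run(self, small_study, scanned):
        """Every planted run-level call is found; nothing else is (error-free reads)."""
        called = small_study.calls.groupby("run_id")["fusion_id"].agg(set).to_dict()
        for run, report in scanned.items():
            assert report.positive_isoforms() == called.get(run, set())

    def test_patient_presence_recovered_exactly(self, small_study, scanned):
        presence = summarize_scan(scanned.values(), small_study.design)
        assert presence == small_study.presence

    def test_scan_derived_association_equals_truth_association(
        self, small_study, scanned
    ):
        import pandas as pd

        presence = summarize_scan(scanned.values(), small_study.design)
        rows = [
            {"run_id": rep.sample_id, "fusion_id": fid}
            for rep in scanned.values()
            for fid in rep.positive_isoforms()
        ]
        scan_calls = pd.DataFrame(rows, columns=["run_id", "fusion_id"])
        res_scan = FusionAssociationModel(scan_calls, small_study.design).fit()
        res_truth = FusionAssociationModel(
            small_study.calls[["run_id", "fusion_id"]], small_study.design
        ).fit()
        pd.testing.assert_frame_equal(
            res_scan.table.drop(columns=["five_prime_gene", "three_prime_gene"]),
            res_truth.table.drop(columns=["five_prime_gene", "three_prime_gene"]),
        )
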