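"""Synthetic study generator: determinism, geometry, truth consistency."""

import numpy as np
import pandas as pd
import pytest

from hfgkit import (
    Category,
    FusionSpec,
    SimulationSpec,
    burden_per_sample,
    classify_fusion,
    collapse_runs_to_patients,
    recurrence_table,
    simulate_annotation,
    simulate_cohorts,
    simulate_reads,
    simulate_study,
)
from hfgkit.cohort import CASE, CONTROL
from hfgkit.simulate import SimulationError, plant_fusions


class TestSimulateAnnotation:
    def test_same_seed_identical_outputs(self):
        spec = SimulationSpec(n_genes=12, seed=21)
        a1, g1 = simulate_annotation(spec)
        a2, g2 = simulate_annotation(spec)
        assert a1 == a2 and g1 == g2
        a3, _ = simulate_annotation(SimulationSpec(n_genes=12, seed=22))
        assert a3 != a1

    def test_genes_do_not_overlap_and_both_strands_present(self):
        ann, genome = simulate_annotation(SimulationSpec(n_genes=30, seed=2))
        by_chrom: dict[str, list] = {}
        for g in ann.values():
            by_chrom.setdefault(g.chrom, []).append(g)
            assert g.end <= len(genome[g.chrom])
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.start)
            for left, right in zip(genes, genes[1:]):
                assert left.end < right.start
        assert {g.strand for g in ann.values()} == {"+", "-"}

    def test_small_gaps_make_readthrough_candidates(self):
        spec = SimulationSpec(n_genes=10, n_chromosomes=1, gap_range=(50_000, 50_000), seed=3)
        ann, _ = simulate_annotation(spec)
        genes = sorted(ann.values(), key=lambda g: g.start)
        from hfgkit import FusionJunction, intergenic_gap

        found_efg = False
        for a, b in zip(genes, genes[1:]):
            assert intergenic_gap(a, b) == 50_000
            if a.strand == b.strand:
                # readthrough runs left-to-right on +, right-to-left on -
                five, three = (a, b) if a.strand == "+" else (b, a)
                fc = classify_fusion(
                    FusionJunction(
                        five.gene_id, three.gene_id,
                        (five.chrom, five.end - 1), (three.chrom, three.start),
                    ),
                    ann,
                )
                assert fc.category is Category.EFG
                found_efg = True
        assert found_efg

    def test_large_gaps_exclude_adjacent_readthrough(self):
        spec = SimulationSpec(n_genes=10, n_chromosomes=1, gap_range=(300_000, 300_000), seed=3)
        ann, _ = simulate_annotation(spec)
        genes = sorted(ann.values(), key=lambda g: g.start)
        from hfgkit import FusionJunction

        for a, b in zip(genes, genes[1:]):
            fc = classify_fusion(
                FusionJunction(a.gene_id, b.gene_id, (a.chrom, a.end - 1), (b.chrom, b.start)),
                ann,
            )
            assert fc.category is Category.GENOMIC

    def test_infeasible_layout_is_an_error(self):
        with pytest.raises(SimulationError, match="chromosome_length"):
            simulate_annotation(SimulationSpec(n_genes=20, chromosome_length=50_000, seed=1))


class TestPlantAndCohorts:
    def test_planted_junctions_classify_to_intended_category(self, small_study):
        for pf in small_study.planted:
            fc = classify_fusion(pf.junction, small_study.annotation)
            assert fc.category.value == pf.spec.category

    def test_roster_geometry_mismatch_rejected_before_sampling(self):
        spec = SimulationSpec(n_genes=8, seed=4)
        ann, genome = simulate_annotation(spec)
        genes = sorted(ann.values(), key=lambda g: (g.chrom, g.start))
        cross = next(
            (a, b) for a in genes for b in genes if a.chrom != b.chrom
        )
        bad = SimulationSpec(
            n_genes=8,
            seed=4,
            roster=(
                FusionSpec("EFG", 0.5, 0.1, cross[0].gene_id, cross[1].gene_id),
            ),
        )
        with pytest.raises(SimulationError, match="classifies as"):
            plant_fusions(bad, ann, genome)

    def test_truth_counts_equal_collapse_plus_recurrence(self, small_study):
        presence = collapse_runs_to_patients(small_study.calls, small_study.design)
        assert presence == small_study.presence
        rec = recurrence_table(presence, small_study.design)
        merged = small_study.truth.merge(
            rec, on=["fusion_id", "cohort"], suffixes=("_truth", "")
        )
        assert len(merged) == len(small_study.truth)
        assert (merged.positive_patients_truth == merged.positive_patients).all()

    def test_every_positive_patient_visible_in_some_run(self, small_study):
        by_patient = small_study.calls.groupby("patient_id")["fusion_id"].agg(set)
        for patient, fusions in small_study.presence.items():
            if fusions:
                assert fusions == by_patient[patient]

    def test_zero_prevalence_fusion_absent_everywhere(self):
        spec = SimulationSpec(
            n_genes=10,
            n_case=15,
            n_control=15,
            seed=6,
            roster=(FusionSpec("EFG", 0.0, 0.0),),
        )
        study = simulate_study(spec)
        assert study.calls.empty
        assert (study.truth.positive_patients == 0).all()

    def test_realized_counts_match_binomial_expectation(self):
        """Mean realized case count over replicates ~ n * prevalence."""
        base = SimulationSpec(
            n_genes=10, seed=9, roster=(FusionSpec("GENOMIC", 0.877, 0.214),)
        )
        ann, genome = simulate_annotation(base)
        planted = plant_fusions(base, ann, genome)
        counts = []
        for rep in range(200):
            spec = SimulationSpec(
                n_genes=10, seed=1000 + rep, roster=base.roster
            )
            study = simulate_cohorts(spec, ann, genome, planted)
            case = study.truth[(study.truth.cohort == CASE)]
            counts.append(int(case.positive_patients.iloc[0]))
        mean = np.mean(counts)
        se = np.sqrt(122 * 0.877 * 0.123) / np.sqrt(200)
        assert abs(mean - 122 * 0.877) <= 3 * se

    def test_prevalence_converges_at_large_cohorts(self):
        spec = SimulationSpec(
            n_genes=10,
            n_case=5000,
            n_control=5000,
            runs_per_case=1,
            seed=10,
            roster=(FusionSpec("GENOMIC", 0.3, 0.6),),
        )
        study = simulate_study(spec)
        t = study.truth.set_index("cohort")
        for cohort, p in ((CASE, 0.3), (CONTROL, 0.6)):
            realized = t.loc[cohort, "positive_patients"] / 5000
            assert abs(realized - p) <= 4 * np.sqrt(p * (1 - p) / 5000)

    def test_expected_burden_recovered(self):
        """Per-patient burden concentrates around the sum of prevalences."""
        n_fusions, prev = 124, 0.8  # expected burden 99.2 per patient
        spec = SimulationSpec(
            n_genes=40,
            n_case=122,
            n_control=4,
            runs_per_case=1,
            seed=12,
            roster=tuple(FusionSpec("GENOMIC", prev, 0.0) for _ in range(n_fusions)),
        )
        study = simulate_study(spec)
        counts, (_, _, mean) = burden_per_sample(study.presence, study.design, cohort=CASE)
        se = np.sqrt(n_fusions * prev * (1 - prev) / 122)
        assert abs(mean - n_fusions * prev) <= 3 * se


class TestSimulateReads:
    def test_byte_identical_under_same_seed(self, tmp_path):
        spec = SimulationSpec(
            n_genes=10, n_case=3, n_control=3, seed=13,
            background_reads_per_run=20, coverage_per_junction=2,
        )
        study1 = simulate_study(spec)
        study2 = simulate_study(spec)
        p1 = simulate_reads(study1, tmp_path / "a", gzip_output=False)
        p2 = simulate_reads(study2, tmp_path / "b", gzip_output=False)
        assert set(p1) == set(p2)
        for run in p1:
            assert p1[run].read_bytes() == p2[run].read_bytes()

    def test_read_length_must_span_probe(self):
        with pytest.raises(SimulationError, match="read_length"):
            SimulationSpec(read_length=40, probe_flank=30)

    def test_substitution_errors_change_reads(self, tmp_path):
        spec = SimulationSpec(
            n_genes=10, n_case=3, n_control=3, seed=13,
            background_reads_per_run=20, coverage_per_junction=2,
        )
        noisy = SimulationSpec(
            n_genes=10, n_case=3, n_control=3, seed=13,
            background_reads_per_run=20, coverage_per_junction=2,
            substitution_rate=0.1,
        )
        clean_paths = simulate_reads(simulate_study(spec), tmp_path / "c", gzip_output=False)
        noisy_paths = simulate_reads(simulate_study(noisy), tmp_path / "n", gzip_output=False)
        run = sorted(clean_paths)[0]
        assert clean_paths[run].read_bytes() != noisy_paths[run].read_bytes()
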