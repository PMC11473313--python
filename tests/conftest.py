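import pytest

from hfgkit import GeneModel, SimulationSpec, simulate_study
from hfgkit.annotation import annotation_from_genes


@pytest.fixture(scope="session")
def toy_annotation():
    """Hand-built annotation covering every classification geometry.

    chr1 (coordinates 0-based half-open):
      A [1000,2000)+   B [2500,3000)+    gap(A,B)=500, readthrough order
      C [1500,3000)+   overlaps A (gap 0)
      D [250000,251000)+  far downstream of A (gap 248000)
      E [2500,3000)-   opposite strand near A
      K [202000,203000)+  gap(A,K) exactly 200000
      H [5000,6000)-   I [3500,4000)-   H->I readthrough on minus strand
    chr2:
      F [1000,2000)+   cross-chromosome partner
    """
    genes = [
        GeneModel("A", "A", "chr1", 1000, 2000, "+"),
        GeneModel("B", "B", "chr1", 2500, 3000, "+"),
        GeneModel("C", "C", "chr1", 1500, 3000, "+"),
        GeneModel("D", "D", "chr1", 250_000, 251_000, "+"),
        GeneModel("E", "E", "chr1", 2500, 3000, "-"),
        GeneModel("K", "K", "chr1", 202_000, 203_000, "+"),
        GeneModel("H", "H", "chr1", 5000, 6000, "-"),
        GeneModel("I", "I", "chr1", 3500, 4000, "-"),
        GeneModel("F", "F", "chr2", 1000, 2000, "+"),
    ]
    return annotation_from_genes(genes)


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study (20 cases x 3 runs vs 30 controls)."""
    spec = SimulationSpec(
        n_case=20,
        n_control=30,
        n_genes=16,
        coverage_per_junction=3,
        background_reads_per_run=50,
        seed=11,
    )
    return simulate_study(spec)


@pytest.fixture(scope="session")
def default_cohort_study():
    """Cohort tables at the emulated study design (122 cases / 252 controls)."""
    return simulate_study(SimulationSpec(seed=5))
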