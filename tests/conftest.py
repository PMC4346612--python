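import numpy as np
import pytest

from epilineage import expression, genomic_io
from epilineage.synthetic import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic genome (seed 42) shared across the suite."""
    return simulate_genome(SimulationConfig(rng_seed=42))


@pytest.fixture(scope="session")
def default_quants(default_dataset):
    """Normalization factors and expression tables for every cell type."""
    ds = default_dataset
    norms, quants = {}, {}
    for ct, track in ds.tracks.items():
        norms[ct] = expression.compute_normalization(track, ds.genes)
        quants[ct] = expression.quantify(track, ds.genes, norms[ct])
    return norms, quants


@pytest.fixture(scope="session")
def opposite_strand_flags(default_dataset):
    return genomic_io.flag_opposite_strand_introns(default_dataset.genes)


@pytest.fixture()
def small_config():
    """A miniature genome for tests that re-simulate."""
    return SimulationConfig(
        n_genes=40,
        chrom_sizes={"1": 700_000},
        n_cassette_exons=6,
        n_retained_introns=10,
        n_umrs_per_cell_type=8,
        rng_seed=7,
    )


def make_track(arrays, library_total=None, assay="rnaseq"):
    data = {c: np.asarray(a, dtype=float) for c, a in arrays.items()}
    t = genomic_io.CoverageTrack(data, assay=assay)
    t.library_total = library_total if library_total is not None else t.total() / 75
    return t
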