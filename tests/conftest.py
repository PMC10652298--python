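import pytest

from synacet import SimulationTruth, gen_peak_deg_tables
from synacet.integrate import (
    assign_primary_cell_type,
    filter_abeta_peaks,
    overlap_with_degs,
    peaks_to_genes,
)


@pytest.fixture(scope="session")
def default_truth():
    return SimulationTruth(seed=11)


@pytest.fixture(scope="session")
def small_tables(default_truth):
    """A compact simulated peak/DEG pair shared across read-only tests."""
    return gen_peak_deg_tables(default_truth, n_genes=500)


@pytest.fixture(scope="session")
def integrated_records(small_tables):
    peaks, degs = small_tables
    gene_map = peaks_to_genes(filter_abeta_peaks(peaks))
    return assign_primary_cell_type(overlap_with_degs(gene_map, degs))
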