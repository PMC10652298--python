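"""Behaviour of the synthetic-data generators against their stated truth."""

import math

import numpy as np
import pytest

from synacet import (
    SimulationTruth,
    gen_ephys_cohort,
    gen_fly_expression,
    gen_homolog_map,
    gen_peak_deg_tables,
    generate_bundle,
)
from synacet.concordance import correlation
from synacet.integrate import filter_abeta_peaks, overlap_with_degs, peaks_to_genes
from synacet.simulate import (
    CellTypeDegProfile,
    SimulationParameterError,
    gen_go_annotations,
    gen_human_expression,
)


def _signal_records(truth, n_genes=500):
    peaks, degs = gen_peak_deg_tables(truth, n_genes=n_genes)
    return overlap_with_degs(peaks_to_genes(filter_abeta_peaks(peaks)), degs)


class TestPeakDegTables:
    def test_determinism(self, default_truth):
        assert gen_peak_deg_tables(default_truth, 400) == \
            gen_peak_deg_tables(default_truth, 400)

    def test_study_like_shape(self, integrated_records, small_tables):
        peaks, _ = small_tables
        significant = filter_abeta_peaks(peaks)
        assert len(peaks_to_genes(significant)) == 329
        assert len(integrated_records) == 100
        assert len({r.gene_symbol for r in integrated_records}) == 87

    def test_direction_counts_exact(self, default_truth, integrated_records):
        for ct, prof in default_truth.celltype_degs.items():
            downs = sum(1 for r in integrated_records
                        if r.cell_type == ct and r.log2fc < 0)
            # concordance tuning may flip at most a few multi-cell-type
            # records' fold changes; direction counts stay within that slack
            assert abs(downs - prof.n_down) <= 2

    def test_null_correlation(self):
        truth = SimulationTruth(rho_true=0.0, same_sign_frac_true=None,
                                n_peak_only_genes=20, n_deg_only_records=0, seed=3)
        recs = _signal_records(truth, n_genes=200)
        r, _ = correlation([x.coef_abeta for x in recs], [x.log2fc for x in recs])
        assert abs(r) < 3.0 / math.sqrt(len(recs))

    def test_full_concordance(self):
        truth = SimulationTruth(rho_true=0.3, same_sign_frac_true=1.0,
                                n_peak_only_genes=20, n_deg_only_records=0, seed=4)
        recs = _signal_records(truth, n_genes=200)
        assert all(r.same_sign for r in recs)

    def test_correlation_recovery_fisher_ci(self):
        # target rho within its own 99% Fisher-z interval at n = 5000 pairs
        prof = {ct: CellTypeDegProfile(p.n_records * 50, p.frac_down)
                for ct, p in SimulationTruth().celltype_degs.items()}
        truth = SimulationTruth(rho_true=0.4, same_sign_frac_true=None,
                                celltype_degs=prof, n_peak_only_genes=20,
                                n_deg_only_records=0, seed=7)
        recs = _signal_records(truth, n_genes=4500)
        r, _ = correlation([x.coef_abeta for x in recs], [x.log2fc for x in recs])
        half = 2.5758 / math.sqrt(len(recs) - 3)
        lo, hi = math.tanh(math.atanh(0.4) - half), math.tanh(math.atanh(0.4) + half)
        assert lo < r < hi

    def test_unattainable_combination_rejected(self):
        with pytest.raises(SimulationParameterError, match="unattainable"):
            SimulationTruth(rho_true=0.6, same_sign_frac_true=0.2)

    def test_n_genes_too_small(self, default_truth):
        with pytest.raises(SimulationParameterError):
            gen_peak_deg_tables(default_truth, n_genes=9)

    def test_fdr_separation(self, small_tables):
        peaks, degs = small_tables
        deg_genes = {d.gene_symbol for d in degs}
        significant = {p.gene_symbol for p in peaks if p.fdr < 0.05}
        assert not any(p.fdr == 0.05 for p in peaks)  # boundary never generated
        assert significant & deg_genes  # signal overlap exists by construction


class TestExpressionGenerators:
    def test_fly_expression_nonnegative_and_deterministic(self, default_truth):
        expr = gen_fly_expression(default_truth, ["dA", "dB"], n_background=50)
        again = gen_fly_expression(default_truth, ["dA", "dB"], n_background=50)
        for ct in expr:
            assert (expr[ct].table["mean_expr"] >= 0).all()
            assert expr[ct].table.equals(again[ct].table)
        assert "perineurial_glia" in expr

    def test_enrichment_boost_applied(self):
        truth = SimulationTruth(enrichment_factor=50.0, seed=9)
        targets = [f"d{i}" for i in range(20)]
        expr = gen_fly_expression(truth, targets, n_background=500)
        pg = expr["perineurial_glia"].table
        other = expr["cortex_glia"].table
        boost = (np.log(pg.loc[targets, "mean_expr"]).mean()
                 - np.log(other.loc[targets, "mean_expr"]).mean())
        assert boost == pytest.approx(np.log(50.0), abs=1.0)

    def test_empty_target_set_rejected(self, default_truth):
        with pytest.raises(SimulationParameterError):
            gen_fly_expression(default_truth, [])

    def test_human_expression_cell_types(self, default_truth):
        expr = gen_human_expression(default_truth, ["A", "B", "C"])
        assert set(expr) == {"Ex", "In", "Ast", "Oli", "OPC", "Mic"}

    def test_go_terms_contain_synaptic_and_other(self, default_truth):
        terms = gen_go_annotations(default_truth, [f"g{i}" for i in range(100)])
        names = [t.term_name.lower() for t in terms]
        assert any("synaptic" in n for n in names)
        assert any("synaptic" not in n for n in names)


class TestHomologMap:
    @pytest.mark.parametrize("coverage,expected", [(1.0, 100), (0.0, 0), (0.5, 50)])
    def test_exact_coverage_count(self, coverage, expected):
        genes = [f"g{i:03d}" for i in range(100)]
        pairs = gen_homolog_map(genes, coverage=coverage, seed=1)
        assert len(pairs) == expected
        assert len({p.human_gene for p in pairs}) == expected  # one fly gene each


class TestEphysCohort:
    def test_gain_algebra_large_n(self):
        truth = SimulationTruth(seed=21, phtx_effect=0.5,
                                genotype_gains={"full": 1.0, "blocked": 0.0})
        cells = gen_ephys_cohort(truth, n_cells_per_group=400)
        from synacet.ephys import summarize_cohort
        by = {s.genotype: s for s in summarize_cohort(cells)}
        assert by["full"].pct_epsp == pytest.approx(100, abs=6)
        assert by["full"].pct_qc == pytest.approx(200, abs=10)
        assert by["blocked"].pct_epsp == pytest.approx(50, abs=4)
        assert by["blocked"].pct_qc == pytest.approx(100, abs=6)

    def test_determinism_and_positivity(self, default_truth):
        a = gen_ephys_cohort(default_truth, 5)
        b = gen_ephys_cohort(default_truth, 5)
        assert a == b
        assert all(c.mepsp_mv > 0 and c.epsp_mv > 0 for c in a)

    def test_invalid_parameters(self):
        with pytest.raises(SimulationParameterError):
            SimulationTruth(phtx_effect=1.5)
        with pytest.raises(SimulationParameterError):
            gen_ephys_cohort(SimulationTruth(), n_cells_per_group=2)


def test_bundle_contains_every_input(default_truth):
    bundle = generate_bundle(default_truth, n_genes=400, n_cells_per_group=4,
                             n_fly_background=200)
    assert {"peaks", "degs", "homologs", "go", "human_expression",
            "fly_expression", "ephys", "annotations"} <= set(bundle)
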