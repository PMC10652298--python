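"""Synaptic-gene selection, fly enrichment bootstrap, cross-species correlation."""

import numpy as np
import pandas as pd
import pytest

from synacet.records import CellTypeExpression, GoAnnotation, HomologPair
from synacet.xspecies import (
    enrichment_percentile,
    expressed_genes,
    resolve_homologs,
    select_synaptic_genes,
    top_n_expressed,
    xspecies_expression_corr,
)


def _expr(cell_type, values, frac=None):
    genes = list(values)
    table = pd.DataFrame({
        "mean_expr": [values[g] for g in genes],
        "frac_expressing": [frac[g] if frac else 0.5 for g in genes],
    }, index=pd.Index(genes, name="gene_symbol"))
    return CellTypeExpression(cell_type, table)


class TestSelectSynapticGenes:
    TERMS = [GoAnnotation("GO:1", "synaptic vesicle cycle", frozenset({"A", "B"})),
             GoAnnotation("GO:2", "myelination", frozenset({"C"})),
             GoAnnotation("GO:3", "Presynaptic assembly", frozenset({"B", "D"}))]

    def test_substring_union_without_duplicates(self):
        assert select_synaptic_genes(self.TERMS) == {"A", "B", "D"}

    def test_case_insensitive_keyword(self):
        assert select_synaptic_genes(self.TERMS, "SYNAPTIC") == {"A", "B", "D"}

    def test_no_match_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no GO term"):
            assert select_synaptic_genes(self.TERMS, "mitochondrial") == set()


class TestTopN:
    def test_top_n_by_expression(self):
        expr = _expr("Ast", {f"g{i}": float(i) for i in range(30)})
        top = top_n_expressed(expr, {f"g{i}" for i in range(30)}, n=20)
        assert len(top) == 20 and top[0] == "g29"

    def test_n_larger_than_candidates_warns(self):
        expr = _expr("Ast", {"a": 1.0, "b": 2.0})
        with pytest.warns(UserWarning, match="only 2"):
            assert top_n_expressed(expr, {"a", "b"}, n=5) == ["b", "a"]

    def test_tie_at_boundary_alphabetical(self):
        expr = _expr("Ast", {"b": 1.0, "a": 1.0, "c": 2.0})
        assert top_n_expressed(expr, {"a", "b", "c"}, n=2) == ["c", "a"]


class TestEnrichmentPercentile:
    def _universe_expr(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        values = {f"g{i:03d}": float(v) for i, v in
                  enumerate(np.sort(rng.lognormal(size=n)))}
        return _expr("perineurial_glia", values), values

    def test_top_targets_hit_percentile_100(self):
        expr, values = self._universe_expr()
        targets = sorted(values, key=values.get)[-10:]
        res = enrichment_percentile(targets, expr, set(values), n_boot=500, seed=1)
        assert res.percentile == 100.0

    def test_seed_reproducibility(self):
        expr, values = self._universe_expr()
        targets = list(values)[:10]
        a = enrichment_percentile(targets, expr, set(values), n_boot=1000, seed=7)
        b = enrichment_percentile(targets, expr, set(values), n_boot=1000, seed=7)
        assert a.percentile == b.percentile

    def test_monotone_in_uniform_target_scaling(self):
        expr, values = self._universe_expr(seed=3)
        targets = list(values)[20:35]
        base = enrichment_percentile(targets, expr, set(values), n_boot=2000, seed=2)
        scaled_tab = expr.table.copy()
        scaled_tab.loc[targets, "mean_expr"] *= 5.0
        scaled = enrichment_percentile(
            targets, CellTypeExpression("perineurial_glia", scaled_tab),
            set(values), n_boot=2000, seed=2)
        assert scaled.percentile >= base.percentile

    def test_universe_smaller_than_targets_rejected(self):
        expr, values = self._universe_expr(n=5)
        with pytest.raises(ValueError, match="larger"):
            enrichment_percentile(list(values), expr, set(values), n_boot=10, seed=0)

    def test_expressed_universe_threshold(self):
        expr = _expr("pg", {"a": 1.0, "b": 2.0, "c": 3.0},
                     frac={"a": 0.005, "b": 0.5, "c": 0.02})
        assert expressed_genes(expr, min_frac=0.01) == {"b", "c"}


class TestCrossSpeciesCorrelation:
    def test_monotone_transform_gives_r_one(self):
        human = _expr("Oli", {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        fly = _expr("pg", {"dA": 0.1, "dB": 0.9, "dC": 5.0, "dD": 100.0})
        pairs = [HomologPair(h, f"d{h}") for h in "ABCD"]
        res = xspecies_expression_corr(human, fly, pairs)
        assert res.spearman_r == pytest.approx(1.0)
        assert res.n_pairs == 4

    def test_frac_expressing_metric(self):
        human = _expr("Oli", {"A": 1.0, "B": 2.0, "C": 3.0})
        fly = _expr("pg", {"dA": 1.0, "dB": 1.0, "dC": 1.0},
                    frac={"dA": 0.9, "dB": 0.5, "dC": 0.1})
        pairs = [HomologPair(h, f"d{h}") for h in "ABC"]
        res = xspecies_expression_corr(human, fly, pairs,
                                       metric="mean_expr_vs_frac_expressing")
        assert res.spearman_r == pytest.approx(-1.0)

    def test_too_few_pairs_raises(self):
        human = _expr("Oli", {"A": 1.0, "B": 2.0})
        fly = _expr("pg", {"dA": 1.0, "dB": 2.0})
        with pytest.raises(ValueError, match=">= 3"):
            xspecies_expression_corr(human, fly,
                                     [HomologPair("A", "dA"), HomologPair("B", "dB")])

    def test_one_to_many_resolved_by_confidence_then_name(self):
        pairs = [HomologPair("A", "dX", 0.5), HomologPair("A", "dY", 0.9),
                 HomologPair("B", "dQ", 0.7), HomologPair("B", "dP", 0.7)]
        assert resolve_homologs(pairs) == {"A": "dY", "B": "dP"}
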