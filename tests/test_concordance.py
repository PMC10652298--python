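"""Same-sign statistics: exact binomial test, correlations, over-representation."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synacet.concordance import (
    concordance_by_scope,
    correlation,
    exact_binomial_two_sided,
    hypergeometric_overrep,
    same_sign,
)
from synacet.records import GoAnnotation, IntegratedRecord


def binomial_p_oracle(k: int, n: int) -> float:
    """Independent enumeration oracle for p0 = 1/2: exact integer comparison
    of binomial coefficients, summed as a rational number."""
    combs = [comb(n, j) for j in range(n + 1)]
    return float(Fraction(sum(c for c in combs if c <= combs[k]), 2 ** n))


class TestSameSign:
    @pytest.mark.parametrize("coef,l2fc,expected", [
        (-0.2, -1.1, True), (0.3, 0.9, True),
        (0.2, -0.1, False), (-0.2, 0.1, False),
        (0.0, 0.5, None), (0.4, 0.0, None), (0.0, 0.0, None),
    ])
    def test_definition(self, coef, l2fc, expected):
        assert same_sign(coef, l2fc) is expected


class TestExactBinomial:
    def test_observed_equals_expectation(self):
        assert exact_binomial_two_sided(50, 100) == pytest.approx(1.0)

    def test_small_case_enumeration(self):
        # n=4, p0=0.5: only pmf(0)=pmf(4)=1/16 are <= pmf(0); p = 2/16
        assert exact_binomial_two_sided(0, 4) == pytest.approx(0.125, abs=1e-12)

    def test_against_enumeration_oracle(self):
        for k, n in [(69, 100), (66, 100), (78, 100), (7, 13), (0, 1), (10, 10)]:
            assert exact_binomial_two_sided(k, n) == \
                pytest.approx(binomial_p_oracle(k, n), abs=1e-10)

    def test_against_scipy_independent_route(self):
        from scipy.stats import binomtest
        for k, n, p0 in [(69, 100, 0.5), (3, 20, 0.3), (17, 20, 0.7)]:
            assert exact_binomial_two_sided(k, n, p0) == \
                pytest.approx(binomtest(k, n, p0).pvalue, rel=1e-9)

    def test_central_method_doubles_tail(self):
        from scipy.stats import binom
        p = exact_binomial_two_sided(3, 20, 0.5, method="central")
        assert p == pytest.approx(2 * binom.cdf(3, 20, 0.5), rel=1e-12)

    @given(n=st.integers(1, 150), k=st.integers(0, 150))
    @settings(max_examples=150, deadline=None)
    def test_symmetry_at_half(self, n, k):
        k = min(k, n)
        assert exact_binomial_two_sided(k, n) == \
            pytest.approx(exact_binomial_two_sided(n - k, n), abs=1e-12)

    @given(n=st.integers(2, 120))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_distance_from_center(self, n):
        ps = [exact_binomial_two_sided(k, n) for k in range(n // 2, n + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_binomial_two_sided(5, 4)
        with pytest.raises(ValueError):
            exact_binomial_two_sided(0, 0)


class TestCorrelation:
    def test_perfect_linear(self):
        r, p = correlation([1, 2, 3], [2, 4, 6], "pearson")
        assert r == pytest.approx(1.0)

    def test_reversed_ranks_spearman(self):
        r, _ = correlation([1, 5, 3, 4], [10, 2, 8, 5], "spearman")
        assert r == pytest.approx(-1.0)

    def test_pearson_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, _ = correlation(x, y, "pearson")
        direct = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r == pytest.approx(direct, abs=1e-12)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="constant"):
            correlation([1, 1, 1], [1, 2, 3])

    @given(st.permutations(list(range(8))),
           st.sampled_from(["exp", "cube", "affine"]))
    @settings(max_examples=40, deadline=None)
    def test_spearman_invariant_under_monotone_transform(self, perm, kind):
        x = np.arange(8.0)
        y = np.array(perm, dtype=float)
        transforms = {"exp": np.exp, "cube": lambda v: v ** 3,
                      "affine": lambda v: 2.5 * v + 1}
        r1, _ = correlation(x, y, "spearman")
        r2, _ = correlation(transforms[kind](x), y, "spearman")
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestConcordanceByScope:
    def test_all_concordant(self):
        recs = [IntegratedRecord(f"G{i}", "Ex", 0.5, float(i + 1), same_sign=True)
                for i in range(5)]
        res = concordance_by_scope(recs)[0]
        assert res.pct_same_sign == 100.0
        assert res.binom_p == pytest.approx(exact_binomial_two_sided(5, 5))

    def test_undefined_records_dropped_from_counts(self):
        recs = [IntegratedRecord("G1", "Ex", 0.5, 1.0, same_sign=True),
                IntegratedRecord("G2", "Ex", 0.0, 1.0, same_sign=None),
                IntegratedRecord("G3", "Ex", -0.5, 1.0, same_sign=False)]
        res = concordance_by_scope(recs)[0]
        assert (res.n, res.k_same_sign) == (2, 1)

    def test_small_scope_has_undefined_correlation(self):
        recs = [IntegratedRecord("G1", "Mic", 0.5, 1.0, same_sign=True),
                IntegratedRecord("G2", "Mic", -0.5, -1.0, same_sign=True)]
        res = [r for r in concordance_by_scope(recs) if r.scope == "Mic"][0]
        assert res.n == 2 and res.pearson_r is None

    def test_scopes_cover_all_plus_cell_types(self, integrated_records):
        scopes = [r.scope for r in concordance_by_scope(integrated_records)]
        assert scopes[0] == "all" and len(scopes) == 7

    def test_recovers_generator_concordance(self, integrated_records, default_truth):
        res = concordance_by_scope(integrated_records)[0]
        se = math.sqrt(0.69 * 0.31 / res.n)
        assert res.pct_same_sign / 100 == pytest.approx(
            default_truth.same_sign_frac_true, abs=2.5 * se)


class TestHypergeometricOverrep:
    def _annotation(self, sets):
        return [GoAnnotation(f"GO:{i}", name, frozenset(genes))
                for i, (name, genes) in enumerate(sets)]

    def test_extreme_and_disjoint(self):
        universe = {f"g{i}" for i in range(50)}
        term = {f"g{i}" for i in range(5)}
        ann = self._annotation([("hit", term), ("miss", {"g40", "g41"})])
        table = hypergeometric_overrep(term, ann, universe).set_index("term_name")
        assert table.loc["hit", "overlap"] == 5
        assert table.loc["miss", "overlap"] == 0
        assert table.loc["miss", "p"] == pytest.approx(1.0)
        assert table.loc["hit", "p"] < table.loc["miss", "p"]

    def test_small_case_matches_enumeration(self):
        # universe 20, term 5, query 5, overlap 3: tail of the hypergeometric pmf
        universe = {f"g{i}" for i in range(20)}
        term = {"g0", "g1", "g2", "g10", "g11"}
        query = {"g0", "g1", "g2", "g15", "g16"}
        expected = sum(comb(5, k) * comb(15, 5 - k) for k in (3, 4, 5)) / comb(20, 5)
        ann = self._annotation([("t", term)])
        p = hypergeometric_overrep(query, ann, universe)["p"].iloc[0]
        assert p == pytest.approx(expected, rel=1e-12)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_overrep({"x"}, self._annotation([("t", {"a"})]), {"a"})
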