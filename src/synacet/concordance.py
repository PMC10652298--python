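"""Sign-concordance statistics between chromatin and transcriptome signals.

The central quantity is the "same sign" flag: a gene is concordant when its
amyloid-pathology coefficient on H3K9ac and its transcriptional log2 fold
change point in the same direction.  Under the null of unrelated signals a
record is concordant with probability 1/2, so the observed concordant count
is tested against Binomial(n, 0.5) with an exact two-sided test.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import CELL_TYPES, ConcordanceResult, GoAnnotation, IntegratedRecord

__all__ = [
    "same_sign",
    "exact_binomial_two_sided",
    "correlation",
    "concordance_by_scope",
    "hypergeometric_overrep",
]

#: Relative tolerance used when comparing point probabilities in the
#: minimum-likelihood two-sided binomial test (guards against floating-point
#: asymmetry between pmf(k) and pmf(n-k)).
_PMF_RELTOL = 1e-7


def same_sign(coef_abeta: float, log2fc: float) -> Optional[bool]:
    """Directional concordance of the two signals.

    True when both are strictly positive or both strictly negative, False
    when they disagree, None (undefined) when either is exactly zero.
    """
    if coef_abeta == 0.0 or log2fc == 0.0:
        return None
    return (coef_abeta > 0) == (log2fc > 0)


def exact_binomial_two_sided(k: int, n: int, p0: float = 0.5,
                             method: str = "minlike") -> float:
    """Exact two-sided binomial p-value for ``k`` successes in ``n`` trials.

    ``method="minlike"`` (default) sums the probabilities of every outcome
    whose point probability does not exceed that of the observed ``k`` —
    the convention used by classical exact binomial tests.  ``method=
    "central"`` doubles the smaller tail probability instead.
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n and n >= 1, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if method == "minlike":
        ks = np.arange(n + 1)
        pmf = stats.binom.pmf(ks, n, p0)
        p = pmf[pmf <= pmf[k] * (1.0 + _PMF_RELTOL)].sum()
    elif method == "central":
        lower = stats.binom.cdf(k, n, p0)
        upper = stats.binom.sf(k - 1, n, p0)
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(min(p, 1.0))


def correlation(x: Sequence[float], y: Sequence[float],
                method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value.

    Spearman uses mid-ranks for ties.  Raises on vectors shorter than 3 or
    with zero variance, where the estimate is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def _scope_result(scope: str, records: list[IntegratedRecord],
                  p0: float, binom_method: str) -> ConcordanceResult:
    defined = [r for r in records if r.same_sign is not None]
    n = len(defined)
    k = sum(1 for r in defined if r.same_sign)
    if n >= 1:
        pct = 100.0 * k / n
        binom_p = exact_binomial_two_sided(k, n, p0, method=binom_method)
    else:
        pct = math.nan
        binom_p = math.nan
    pearson_r = pearson_p = None
    if n >= 3:
        x = [r.coef_abeta for r in defined]
        y = [r.log2fc for r in defined]
        try:
            pearson_r, pearson_p = correlation(x, y, "pearson")
        except ValueError:
            pass  # constant vector: leave undefined
    return ConcordanceResult(scope=scope, n=n, k_same_sign=k, pct_same_sign=pct,
                             binom_p=binom_p, pearson_r=pearson_r, pearson_p=pearson_p)


def concordance_by_scope(records: Iterable[IntegratedRecord], p0: float = 0.5,
                         binom_method: str = "minlike") -> list[ConcordanceResult]:
    """Concordance summary for all records pooled and per cell type.

    Records with an undefined same-sign flag (either signal exactly zero)
    are excluded from both the concordant count and the trial count, and
    from the correlation.  Scopes with fewer than 3 usable records report
    counts but an undefined correlation.
    """
    records = list(records)
    results = [_scope_result("all", records, p0, binom_method)]
    for ct in CELL_TYPES:
        ct_records = [r for r in records if r.cell_type == ct]
        if ct_records:
            results.append(_scope_result(ct, ct_records, p0, binom_method))
    return results


def concordance_table(results: Iterable[ConcordanceResult]) -> pd.DataFrame:
    """Tabular view of :func:`concordance_by_scope` output."""
    return pd.DataFrame([{
        "scope": r.scope, "n": r.n, "k_same_sign": r.k_same_sign,
        "pct_same_sign": r.pct_same_sign, "binom_p": r.binom_p,
        "pearson_r": r.pearson_r, "pearson_p": r.pearson_p,
    } for r in results])


def hypergeometric_overrep(query: Iterable[str], annotation: Iterable[GoAnnotation],
                           universe: Iterable[str]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` per GO term.

    Returns a DataFrame (term_id, term_name, n_term, overlap, p, p_adj)
    sorted by p; ``p_adj`` is Benjamini-Hochberg across the supplied terms.
    Term gene sets are intersected with the universe before testing.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for term in annotation:
        term_genes = term.genes & universe
        m = len(term_genes)
        k = len(term_genes & query)
        # P(X >= k) for X ~ Hypergeom(N=|universe|, K=m, n=|query|)
        p = float(stats.hypergeom.sf(k - 1, len(universe), m, len(query))) if m else 1.0
        rows.append({"term_id": term.term_id, "term_name": term.term_name,
                     "n_term": m, "overlap": k, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        table["p_adj"] = []
    return table
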