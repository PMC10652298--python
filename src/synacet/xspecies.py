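"""Cross-species synaptic-gene enrichment in fly perineurial glia.

Selects the most highly expressed "synaptic" genes per human cell type,
maps them to fly homologues, and asks — by resampling random expressed
genes — whether those homologues are more highly expressed in perineurial
glia than expected by chance, and whether their expression levels track
the human ones.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional

import numpy as np

from .concordance import correlation
from .records import (
    CellTypeExpression,
    EnrichmentResult,
    GoAnnotation,
    HomologPair,
    XSpeciesCorrResult,
)

__all__ = [
    "select_synaptic_genes",
    "top_n_expressed",
    "expressed_genes",
    "resolve_homologs",
    "enrichment_percentile",
    "xspecies_expression_corr",
]


def select_synaptic_genes(annotations: Iterable[GoAnnotation],
                          keyword: str = "synaptic") -> set[str]:
    """Union of gene sets of all GO terms whose name contains ``keyword``
    (case-insensitive substring match)."""
    key = keyword.lower()
    out: set[str] = set()
    matched = False
    for term in annotations:
        if key in term.term_name.lower():
            matched = True
            out |= term.genes
    if not matched:
        warnings.warn(f"no GO term name contains keyword {keyword!r}; "
                      "returning empty gene set")
    return out


def top_n_expressed(expr: CellTypeExpression, candidates: Iterable[str],
                    n: int = 20) -> list[str]:
    """The ``n`` candidate genes with highest mean expression in this cell
    type, descending; ties broken alphabetically."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    present = sorted(set(candidates) & expr.genes)
    if len(present) < n:
        warnings.warn(f"only {len(present)} of the requested top {n} candidate "
                      f"genes are present in {expr.cell_type}; returning all")
    ranked = sorted(present, key=lambda g: (-float(expr.table.at[g, "mean_expr"]), g))
    return ranked[:n]


def expressed_genes(expr: CellTypeExpression, min_frac: float = 0.01) -> set[str]:
    """Genes counted as expressed: fraction-expressing strictly above
    ``min_frac`` (default 1% of cells)."""
    frac = expr.table["frac_expressing"]
    return set(frac.index[frac > min_frac])


def resolve_homologs(pairs: Iterable[HomologPair]) -> dict[str, str]:
    """One fly homologue per human gene.

    One-to-many relations are resolved by highest confidence, then
    alphabetically by fly gene name.
    """
    best: dict[str, HomologPair] = {}
    for p in pairs:
        prev = best.get(p.human_gene)
        if prev is None or (-p.confidence, p.fly_gene) < (-prev.confidence, prev.fly_gene):
            best[p.human_gene] = p
    return {h: p.fly_gene for h, p in best.items()}


def _gene_values(expr: CellTypeExpression, genes: list[str],
                 specificity_of: Optional[Mapping[str, CellTypeExpression]]) -> np.ndarray:
    values = expr.table["mean_expr"].loc[genes].to_numpy(dtype=float)
    if specificity_of is not None:
        total = np.zeros(len(genes))
        for other in specificity_of.values():
            total += other.table["mean_expr"].reindex(genes).fillna(0.0).to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(total > 0, values / total, 0.0)
    return values


def enrichment_percentile(target_fly_genes: Iterable[str],
                          fly_expr: CellTypeExpression,
                          expressed_universe: Iterable[str],
                          n_boot: int = 10_000,
                          seed: int = 0,
                          human_cell_type: str = "",
                          n_top: Optional[int] = None,
                          specificity_of: Optional[Mapping[str, CellTypeExpression]] = None,
                          ) -> EnrichmentResult:
    """Bootstrap percentile of a gene set's expression in one fly cell type.

    The statistic is the mean expression of the target genes in
    ``fly_expr`` (optionally EWCE-style specificity — expression divided by
    its sum over the cell types in ``specificity_of``).  The null is the
    same statistic for ``n_boot`` random same-size subsets of the expressed
    universe, drawn without replacement.  The percentile is the fraction of
    null draws strictly below the observed statistic (x100); null draws
    tying the observed value count as not-below.
    """
    targets = sorted(set(target_fly_genes))
    universe = sorted(set(expressed_universe))
    if not targets:
        raise ValueError("target gene set must be non-empty")
    if not set(targets) <= set(universe):
        missing = sorted(set(targets) - set(universe))[:5]
        raise ValueError(f"target genes not in the expressed universe: {missing} ...")
    if len(universe) <= len(targets):
        raise ValueError(f"expressed universe ({len(universe)}) must be larger "
                         f"than the target set ({len(targets)})")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    observed = float(np.mean(_gene_values(fly_expr, targets, specificity_of)))
    pool = _gene_values(fly_expr, universe, specificity_of)
    rng = np.random.default_rng(seed)
    k, n_uni = len(targets), len(pool)
    null = np.empty(n_boot)
    # chunked vectorized subsampling without replacement (argpartition of
    # random keys), keeping memory bounded
    chunk = max(1, int(2e7) // max(n_uni, 1))
    done = 0
    while done < n_boot:
        take = min(chunk, n_boot - done)
        keys = rng.random((take, n_uni))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null[done:done + take] = pool[idx].mean(axis=1)
        done += take
    percentile = 100.0 * float(np.mean(null < observed))
    return EnrichmentResult(human_cell_type=human_cell_type,
                            n_top=n_top if n_top is not None else k,
                            n_mapped=k, percentile=percentile,
                            n_boot=n_boot, seed=seed)


def xspecies_expression_corr(human_expr: CellTypeExpression,
                             fly_expr: CellTypeExpression,
                             gene_pairs: Iterable[HomologPair],
                             metric: str = "mean_expr_vs_mean_expr",
                             ) -> XSpeciesCorrResult:
    """Spearman correlation between human expression and fly-homologue
    expression (or fraction of fly cells expressing) in one fly cell type.

    Only homologue pairs present in both summaries contribute; at least 3
    such pairs are required.
    """
    if metric not in ("mean_expr_vs_mean_expr", "mean_expr_vs_frac_expressing"):
        raise ValueError(f"unknown metric {metric!r}")
    mapping = resolve_homologs(gene_pairs)
    human_vals, fly_vals = [], []
    fly_col = "mean_expr" if metric == "mean_expr_vs_mean_expr" else "frac_expressing"
    for human_gene in sorted(mapping):
        fly_gene = mapping[human_gene]
        if human_gene in human_expr.genes and fly_gene in fly_expr.genes:
            human_vals.append(float(human_expr.table.at[human_gene, "mean_expr"]))
            fly_vals.append(float(fly_expr.table.at[fly_gene, fly_col]))
    if len(human_vals) < 3:
        raise ValueError(f"need >= 3 mapped homologue pairs with expression in both "
                         f"species, got {len(human_vals)}")
    r, p = correlation(human_vals, fly_vals, method="spearman")
    return XSpeciesCorrResult(human_cell_type=human_expr.cell_type,
                              spearman_r=r, p=p, metric=metric,
                              n_pairs=len(human_vals))
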