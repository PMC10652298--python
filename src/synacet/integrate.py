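"""Epigenome-transcriptome integration.

Filters amyloid-associated H3K9ac peaks, collapses peaks to genes, joins
the gene-level chromatin signal with cell-type-resolved differential
expression, assigns each multi-DEG gene a primary cell type, and tabulates
per-cell-type regulation direction.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .concordance import same_sign
from .records import CELL_TYPES, DegRecord, IntegratedRecord, PeakRecord

__all__ = [
    "filter_abeta_peaks",
    "peaks_to_genes",
    "overlap_with_degs",
    "assign_primary_cell_type",
    "per_celltype_direction_counts",
]


def filter_abeta_peaks(peaks: Iterable[PeakRecord], fdr_max: float = 0.05) -> list[PeakRecord]:
    """Peaks significantly associated with amyloid pathology (fdr strictly
    below ``fdr_max``), in the original order."""
    return [p for p in peaks if p.fdr < fdr_max]


def peaks_to_genes(peaks: Iterable[PeakRecord]) -> dict[str, PeakRecord]:
    """Collapse peaks to one representative peak per gene.

    When several peaks annotate the same gene the one with the smallest FDR
    supplies the gene's amyloid coefficient and chromatin state; FDR ties
    fall back to the largest |coef_abeta|, then to file order.  Input is
    expected to be already significance-filtered.
    """
    best: dict[str, tuple] = {}
    for pos, peak in enumerate(peaks):
        key = (peak.fdr, -abs(peak.coef_abeta), pos)
        prev = best.get(peak.gene_symbol)
        if prev is None or key < prev[0]:
            best[peak.gene_symbol] = (key, peak)
    return {gene: peak for gene, (_, peak) in best.items()}


def overlap_with_degs(gene_map: Mapping[str, PeakRecord],
                      degs: Iterable[DegRecord]) -> list[IntegratedRecord]:
    """Join gene-level chromatin signal with DEG records.

    The unit of analysis is the (gene, cell type) record: a gene that is a
    DEG in several cell types yields several integrated records, all sharing
    the gene's amyloid coefficient.  DEG order is preserved.
    """
    out = []
    for deg in degs:
        peak = gene_map.get(deg.gene_symbol)
        if peak is None:
            continue
        out.append(IntegratedRecord(
            gene_symbol=deg.gene_symbol, cell_type=deg.cell_type,
            coef_abeta=peak.coef_abeta, log2fc=deg.log2fc,
            same_sign=same_sign(peak.coef_abeta, deg.log2fc)))
    return out


def assign_primary_cell_type(records: Iterable[IntegratedRecord]) -> list[IntegratedRecord]:
    """Flag, per gene, the record with the largest |log2fc| as primary.

    Exact |log2fc| ties are broken by the fixed cell-type order
    (Ex, In, Ast, Oli, OPC, Mic) so the assignment is deterministic and
    invariant under permutation of the input.
    """
    records = list(records)
    best_by_gene: dict[str, tuple] = {}
    for r in records:
        key = (-abs(r.log2fc), CELL_TYPES.index(r.cell_type))
        prev = best_by_gene.get(r.gene_symbol)
        if prev is None or key < prev[0]:
            best_by_gene[r.gene_symbol] = (key, r)
    winners = {id(r) for _, r in best_by_gene.values()}
    return [IntegratedRecord(gene_symbol=r.gene_symbol, cell_type=r.cell_type,
                             coef_abeta=r.coef_abeta, log2fc=r.log2fc,
                             same_sign=r.same_sign, is_primary=id(r) in winners)
            for r in records]


def per_celltype_direction_counts(records: Iterable[IntegratedRecord]) -> pd.DataFrame:
    """Per-cell-type totals and regulation-direction breakdown.

    Returns a DataFrame indexed by cell type (fixed order, only cell types
    present) with columns n_total, n_up, n_down, pct_down, pct_up.  Records
    with log2fc exactly 0 count toward n_total but neither direction.
    """
    records = list(records)
    rows = []
    for ct in CELL_TYPES:
        ct_records = [r for r in records if r.cell_type == ct]
        if not ct_records:
            continue
        n_total = len(ct_records)
        n_up = sum(1 for r in ct_records if r.log2fc > 0)
        n_down = sum(1 for r in ct_records if r.log2fc < 0)
        rows.append({"cell_type": ct, "n_total": n_total, "n_up": n_up, "n_down": n_down,
                     "pct_down": 100.0 * n_down / n_total,
                     "pct_up": 100.0 * n_up / n_total})
    table = pd.DataFrame(rows, columns=["cell_type", "n_total", "n_up", "n_down",
                                        "pct_down", "pct_up"])
    return table.set_index("cell_type")
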