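"""Domain types shared across the pipeline.

Every record validates its own invariants on construction, so downstream
stages can assume well-formed inputs.  Genomic coordinates follow the BED
convention (0-based, half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

#: Human brain cell types, in the fixed order used for deterministic
#: tie-breaking throughout the pipeline: excitatory neurons, inhibitory
#: neurons, astrocytes, oligodendrocytes, oligodendrocyte progenitors,
#: microglia.
CELL_TYPES = ("Ex", "In", "Ast", "Oli", "OPC", "Mic")

CHROMATIN_STATES = ("promoter", "enhancer", "other")

PHTX_CONDITIONS = ("absent", "present")


class RecordValidationError(ValueError):
    """An input record violates a domain invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise RecordValidationError(msg)


@dataclass
class PeakRecord:
    """One H3K9ac ChIP-seq peak with its amyloid-pathology regression result.

    ``coef_abeta`` quantifies how the peak's acetylation signal varies with
    amyloid-beta burden across donors; ``fdr`` is the false-discovery-rate
    adjusted significance of that association.
    """

    peak_id: str
    chrom: str
    start: int
    end: int
    gene_symbol: str
    chromatin_state: str
    coef_abeta: float
    fdr: float

    def __post_init__(self) -> None:
        _require(bool(self.peak_id), "peak_id must be non-empty")
        _require(bool(self.gene_symbol), f"peak {self.peak_id}: gene_symbol must be non-empty")
        _require(self.start < self.end,
                 f"peak {self.peak_id}: start ({self.start}) must be < end ({self.end})")
        _require(self.chromatin_state in CHROMATIN_STATES,
                 f"peak {self.peak_id}: unknown chromatin_state {self.chromatin_state!r}")
        _require(0.0 <= self.fdr <= 1.0,
                 f"peak {self.peak_id}: fdr {self.fdr} outside [0, 1]")


@dataclass
class DegRecord:
    """One cell-type-resolved differential-expression result (AD vs control)."""

    gene_symbol: str
    cell_type: str
    log2fc: float
    adj_p: float

    def __post_init__(self) -> None:
        _require(bool(self.gene_symbol), "gene_symbol must be non-empty")
        _require(self.cell_type in CELL_TYPES,
                 f"DEG {self.gene_symbol}: unknown cell_type {self.cell_type!r}")
        _require(0.0 <= self.adj_p <= 1.0,
                 f"DEG {self.gene_symbol}/{self.cell_type}: adj_p {self.adj_p} outside [0, 1]")


@dataclass
class IntegratedRecord:
    """The joined unit of analysis: one gene x cell type with both signals.

    ``same_sign`` is True when the amyloid coefficient and the transcriptional
    log2 fold change point in the same direction, None (undefined) when either
    is exactly zero.  ``is_primary`` marks the single cell type a multi-DEG
    gene is assigned to (largest |log2fc|).
    """

    gene_symbol: str
    cell_type: str
    coef_abeta: float
    log2fc: float
    same_sign: Optional[bool] = None
    is_primary: bool = False

    def __post_init__(self) -> None:
        _require(bool(self.gene_symbol), "gene_symbol must be non-empty")
        _require(self.cell_type in CELL_TYPES,
                 f"{self.gene_symbol}: unknown cell_type {self.cell_type!r}")
        defined = self.coef_abeta != 0.0 and self.log2fc != 0.0
        if defined:
            expected = (self.coef_abeta > 0) == (self.log2fc > 0)
            _require(self.same_sign == expected,
                     f"{self.gene_symbol}/{self.cell_type}: same_sign flag inconsistent "
                     f"with coef_abeta={self.coef_abeta}, log2fc={self.log2fc}")
        else:
            _require(self.same_sign is None,
                     f"{self.gene_symbol}/{self.cell_type}: same_sign must be undefined "
                     "when either value is exactly 0")


@dataclass
class HomologPair:
    """A human gene and its fly homologue with a mapping confidence score."""

    human_gene: str
    fly_gene: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        _require(bool(self.human_gene) and bool(self.fly_gene),
                 "homolog pair gene names must be non-empty")
        _require(self.confidence >= 0, f"{self.human_gene}: confidence must be >= 0")


@dataclass
class GoAnnotation:
    """One Gene Ontology term and its annotated gene set."""

    term_id: str
    term_name: str
    genes: frozenset

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        _require(bool(self.term_id), "term_id must be non-empty")
        _require(len(self.genes) > 0, f"GO term {self.term_id}: gene set must be non-empty")


@dataclass
class EphysCell:
    """Per-cell intracellular recording at the fly neuromuscular junction.

    Amplitudes are in mV; ``phtx`` states whether philanthotoxin (the
    glutamate-receptor antagonist used to trigger homeostatic potentiation)
    was present in the bath.
    """

    genotype: str
    phtx: str
    mepsp_mv: float
    epsp_mv: float

    def __post_init__(self) -> None:
        _require(bool(self.genotype), "genotype must be non-empty")
        _require(self.phtx in PHTX_CONDITIONS,
                 f"{self.genotype}: phtx must be one of {PHTX_CONDITIONS}, got {self.phtx!r}")
        _require(self.mepsp_mv > 0, f"{self.genotype}: mepsp_mv must be > 0")
        _require(self.epsp_mv > 0, f"{self.genotype}: epsp_mv must be > 0")


@dataclass
class CellTypeExpression:
    """Per-gene expression summary for one cell type.

    ``table`` is indexed by gene symbol with columns ``mean_expr``
    (normalized expression, >= 0) and ``frac_expressing`` (fraction of cells
    of this type expressing the gene, in [0, 1]).
    """

    cell_type: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        _require(bool(self.cell_type), "cell_type must be non-empty")
        missing = {"mean_expr", "frac_expressing"} - set(self.table.columns)
        _require(not missing, f"{self.cell_type}: expression table missing columns {missing}")
        if len(self.table):
            _require(bool((self.table["mean_expr"] >= 0).all()),
                     f"{self.cell_type}: mean_expr must be >= 0")
            frac = self.table["frac_expressing"]
            _require(bool(((frac >= 0) & (frac <= 1)).all()),
                     f"{self.cell_type}: frac_expressing must be in [0, 1]")
        _require(self.table.index.is_unique,
                 f"{self.cell_type}: duplicate gene symbols in expression table")

    @property
    def genes(self) -> frozenset:
        return frozenset(self.table.index)

    def mean_expr(self, genes=None) -> pd.Series:
        s = self.table["mean_expr"]
        return s if genes is None else s.loc[list(genes)]

    def frac_expressing(self, genes=None) -> pd.Series:
        s = self.table["frac_expressing"]
        return s if genes is None else s.loc[list(genes)]


# ---------------------------------------------------------------------------
# Result containers


@dataclass
class ConcordanceResult:
    """Sign-concordance and correlation summary for one scope.

    ``scope`` is "all" or one cell type; ``n`` counts records with a defined
    same-sign flag, ``k_same_sign`` of which are concordant.  ``binom_p`` is
    the exact two-sided binomial p-value against 50% concordance.
    """

    scope: str
    n: int
    k_same_sign: int
    pct_same_sign: float
    binom_p: float
    pearson_r: Optional[float]
    pearson_p: Optional[float]


@dataclass
class EnrichmentResult:
    """Bootstrap expression-enrichment of a gene set in one fly cell type."""

    human_cell_type: str
    n_top: int
    n_mapped: int
    percentile: float
    n_boot: int
    seed: int


@dataclass
class XSpeciesCorrResult:
    """Cross-species expression correlation for one human cell type."""

    human_cell_type: str
    spearman_r: float
    p: float
    metric: str
    n_pairs: int


@dataclass
class GenotypeSummary:
    """Per-genotype homeostatic-plasticity metrics.

    Percentages express the +PhTX group mean as a percent of the -PhTX
    (baseline) group mean of the same genotype.  ``php_intact`` is True when
    quantal content rises significantly under PhTX.
    """

    genotype: str
    n_minus: int
    n_plus: int
    mean_mepsp_minus: float
    mean_mepsp_plus: float
    mean_epsp_minus: float
    mean_epsp_plus: float
    mean_qc_minus: float
    mean_qc_plus: float
    pct_mepsp: float
    pct_epsp: float
    pct_qc: float
    qc_p: float
    php_intact: bool
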