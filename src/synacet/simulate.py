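"""Synthetic input generator with controllable ground truth.

Emulates every table the pipeline consumes: the H3K9ac peak table, the
cell-type-resolved DEG table, human and fly per-cell-type expression
summaries, a human-fly homologue map, a GO annotation table, and a
per-cell electrophysiology cohort.  All generators are pure functions of
(truth, seed): one global seed fans out into independent per-generator
substreams, so regenerating any table is byte-identical.

Statistical structure of the peak/DEG generator
-----------------------------------------------
Per gene, the amyloid coefficient and transcriptional log2 fold change are
drawn from a Gaussian copula with correlation ``rho_gen``.  Regulation
direction is then imposed per cell type (exact down-regulated counts) by
folding each pair into the demanded half-plane — negating (coef, log2fc)
jointly, which preserves both the correlation structure and the sign
concordance probability.  Because folding with an unbalanced up/down split
attenuates the pooled Pearson correlation by the analytically known factor
sqrt((1-d)/(1-rho^2 d)) with d = (1-2w)^2 * 2/pi (w = overall down
fraction), ``rho_gen`` is pre-calibrated so the pooled population
correlation equals ``rho_true`` exactly.

Sign concordance is tuned independently: under the copula a record is
concordant with probability f0 = 1/2 + arcsin(rho_gen)/pi; to reach a
target fraction f, discordant records are made concordant (or vice versa)
by flipping the amyloid coefficient's sign with the Bernoulli probability
that makes the expected concordance equal f.  Per-record independence of
these flips keeps the concordant count Binomial(n, f), which is what
calibration studies of the binomial test require.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from . import io as sio
from .records import (
    CELL_TYPES,
    CHROMATIN_STATES,
    CellTypeExpression,
    DegRecord,
    EphysCell,
    GoAnnotation,
    HomologPair,
    PeakRecord,
)

__all__ = [
    "SimulationParameterError",
    "CellTypeDegProfile",
    "SimulationTruth",
    "gen_peak_deg_tables",
    "gen_fly_expression",
    "gen_human_expression",
    "gen_go_annotations",
    "gen_homolog_map",
    "gen_ephys_cohort",
    "gen_genotype_annotations",
    "generate_bundle",
    "write_bundle",
]


class SimulationParameterError(ValueError):
    """A requested ground-truth parameter combination is unattainable."""


@dataclass(frozen=True)
class CellTypeDegProfile:
    """Number of DEG records and their down-regulated fraction for one cell type."""

    n_records: int
    frac_down: float

    def __post_init__(self):
        if self.n_records < 0:
            raise SimulationParameterError("n_records must be >= 0")
        if not 0.0 <= self.frac_down <= 1.0:
            raise SimulationParameterError("frac_down must be in [0, 1]")

    @property
    def n_down(self) -> int:
        return round(self.frac_down * self.n_records)


#: Default per-cell-type DEG profile: 100 records over 87 genes with the
#: direction structure reported for the AD integration (77% of excitatory-
#: neuron DEGs down, all inhibitory-neuron DEGs down, 70% of oligodendrocyte
#: DEGs up, 67% of microglial DEGs down).
DEFAULT_CELLTYPE_DEGS: Mapping[str, CellTypeDegProfile] = {
    "Ex": CellTypeDegProfile(35, 27 / 35),
    "In": CellTypeDegProfile(13, 1.0),
    "Ast": CellTypeDegProfile(9, 5 / 9),
    "Oli": CellTypeDegProfile(27, 8 / 27),
    "OPC": CellTypeDegProfile(7, 4 / 7),
    "Mic": CellTypeDegProfile(9, 6 / 9),
}

#: Default homeostatic gain per genotype: a wild type with full presynaptic
#: compensation, nine loss-of-function mutants with (near-)blocked
#: potentiation, and motoneuron-specific knockdowns with partial block.
DEFAULT_GENOTYPE_GAINS: Mapping[str, float] = {
    "wt": 1.0,
    "Septin5": 0.02,
    "CG42709": 0.05,
    "h": 0.08,
    "dpn": 0.0,
    "E2f1": 0.02,
    "NimC1": 0.05,
    "M6": 0.0,
    "Mkp3": 0.10,
    "Cep97": 0.08,
    "dpn_neural_RNAi": 0.60,
    "NimC1_neural_RNAi": 0.55,
    "M6_neural_RNAi": 0.90,
}

DEFAULT_FLY_CELL_TYPES = ("perineurial_glia", "cortex_glia", "ensheathing_glia",
                          "astrocyte_like")

_STREAMS = {
    "peaks_degs": 0,
    "fly_expr": 1,
    "human_expr": 2,
    "go": 3,
    "homologs": 4,
    "ephys": 5,
    "annotations": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],)))


@dataclass
class SimulationTruth:
    """Ground-truth parameters driving every generator.

    rho_true
        Target pooled Pearson correlation between the amyloid coefficient
        and log2 fold change over integrated records, in (-1, 1).
    same_sign_frac_true
        Target per-record sign-concordance probability; ``None`` leaves the
        copula's natural concordance 1/2 + arcsin(rho)/pi untouched.
    celltype_degs
        Per-cell-type record counts and down-regulated fractions.
    multi_celltype_frac
        Fraction of DEG records that are a gene's second cell type (the
        source of the records-vs-distinct-genes gap).
    enrichment_factor
        Multiplicative over-expression of target genes in fly perineurial
        glia (>= 1; 1 means no enrichment).
    genotype_gains
        Homeostatic gain per genotype: the fraction of the PhTX-induced
        quantal-size reduction compensated by extra release (1 = full
        compensation, 0 = blocked).
    phtx_effect
        Multiplicative mEPSP reduction by philanthotoxin, in (0, 1).
    """

    rho_true: float = 0.37
    same_sign_frac_true: Optional[float] = 0.69
    celltype_degs: Mapping[str, CellTypeDegProfile] = field(
        default_factory=lambda: dict(DEFAULT_CELLTYPE_DEGS))
    multi_celltype_frac: float = 0.13
    enrichment_factor: float = 10.0
    genotype_gains: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_GAINS))
    phtx_effect: float = 0.5
    seed: int = 0
    # table-scale knobs (study-like defaults: 329 amyloid-associated genes
    # of which 87 are DEGs; a larger body of DEGs without significant peaks)
    n_peak_only_genes: int = 242
    n_deg_only_records: int = 400
    extra_peak_frac: float = 0.25
    coef_scale: float = 0.4
    log2fc_scale: float = 0.5
    # electrophysiology baselines: wild-type-like quantal size and content
    mepsp0_mv: float = 0.8
    qc0: float = 45.0
    ephys_cv: float = 0.15

    def __post_init__(self):
        if not -0.99 <= self.rho_true <= 0.99:
            raise SimulationParameterError(f"rho_true must be in [-0.99, 0.99], got {self.rho_true}")
        f = self.same_sign_frac_true
        if f is not None:
            if not 0.0 <= f <= 1.0:
                raise SimulationParameterError(f"same_sign_frac_true must be in [0, 1], got {f}")
            # Concordance is tuned by sign flips; asking for concordance that
            # contradicts the direction of the requested correlation would
            # require flips that destroy the correlation's sign.
            if (self.rho_true > 0.05 and f < 0.45) or (self.rho_true < -0.05 and f > 0.55):
                raise SimulationParameterError(
                    f"unattainable combination: rho_true={self.rho_true} with "
                    f"same_sign_frac_true={f} (concordance target contradicts the "
                    "correlation's direction)")
        if not 0.0 < self.phtx_effect < 1.0:
            raise SimulationParameterError(
                f"phtx_effect must be in (0, 1), got {self.phtx_effect}")
        for g, gain in self.genotype_gains.items():
            if not 0.0 <= gain <= 1.0:
                raise SimulationParameterError(f"gain for {g!r} must be in [0, 1], got {gain}")
        if self.enrichment_factor < 1.0:
            raise SimulationParameterError(
                f"enrichment_factor must be >= 1, got {self.enrichment_factor}")
        if not 0.0 <= self.multi_celltype_frac <= 0.5:
            raise SimulationParameterError("multi_celltype_frac must be in [0, 0.5]")
        for ct in self.celltype_degs:
            if ct not in CELL_TYPES:
                raise SimulationParameterError(f"unknown cell type {ct!r} in celltype_degs")

    @property
    def n_records(self) -> int:
        return sum(p.n_records for p in self.celltype_degs.values())

    @property
    def overall_frac_down(self) -> float:
        m = self.n_records
        return sum(p.n_down for p in self.celltype_degs.values()) / m if m else 0.0


def _calibrated_rho(rho_true: float, frac_down: float) -> float:
    """Copula correlation whose post-folding pooled Pearson equals rho_true."""
    d = (1.0 - 2.0 * frac_down) ** 2 * (2.0 / math.pi)
    rho_gen = rho_true / math.sqrt(1.0 - d * (1.0 - rho_true ** 2))
    if abs(rho_gen) >= 1.0:
        raise SimulationParameterError(
            f"rho_true={rho_true} unattainable with overall down fraction {frac_down}")
    return rho_gen


# ---------------------------------------------------------------------------
# Peak + DEG tables


def gen_peak_deg_tables(truth: SimulationTruth,
                        n_genes: int = 2000) -> tuple[list[PeakRecord], list[DegRecord]]:
    """Generate matched H3K9ac peak and DEG tables over ``n_genes`` genes.

    "Signal" genes carry both a significant amyloid-associated peak
    (FDR < 0.05) and one or two DEG records whose (coef, log2fc) pairs obey
    the truth's correlation, concordance and direction structure.  The rest
    of the universe is filled with significant peak-only genes, DEG-only
    genes, and decoy peaks with FDR >= 0.05.
    """
    if n_genes < 10:
        raise SimulationParameterError(f"n_genes must be >= 10, got {n_genes}")
    rng = _rng(truth.seed, "peaks_degs")

    # --- record slots with exact per-cell-type down counts
    slots: list[tuple[str, int]] = []
    for ct in CELL_TYPES:
        prof = truth.celltype_degs.get(ct)
        if prof is None or prof.n_records == 0:
            continue
        dirs = np.concatenate([-np.ones(prof.n_down), np.ones(prof.n_records - prof.n_down)])
        rng.shuffle(dirs)
        slots.extend((ct, int(d)) for d in dirs)
    m = len(slots)
    if m == 0:
        raise SimulationParameterError("celltype_degs defines no DEG records")
    order = rng.permutation(m)
    slots = [slots[i] for i in order]

    # --- copula draws with direction folding
    #
    # Each gene's (coef, log2fc) pair is folded jointly — negated when the
    # realized log2fc sign disagrees with the slot's demanded direction —
    # which preserves the correlation structure the calibration accounts
    # for.  A gene with a second cell type shares its coefficient: the gene
    # is folded by its first record, and the second record's value is left
    # untouched; instead it is *assigned* to a still-open slot whose
    # demanded direction matches the realized sign (different cell type),
    # so exact per-cell-type direction counts hold without distorting the
    # joint law.  Only when no matching slot remains is the second value's
    # sign flipped to fit (a rare, order-of-few-records correction).
    n_dup = int(round(truth.multi_celltype_frac * m))
    rho_gen = _calibrated_rho(truth.rho_true, truth.overall_frac_down)
    resid = math.sqrt(1.0 - rho_gen ** 2)
    order = list(rng.permutation(m))
    available = [True] * m
    ptr = 0

    def _pop_next() -> int:
        nonlocal ptr
        while not available[order[ptr]]:
            ptr += 1
        idx = order[ptr]
        available[idx] = False
        return idx

    def _pop_matching(want_dir: int | None, avoid_ct: str) -> int | None:
        for idx in order:
            if available[idx] and slots[idx][0] != avoid_ct and \
                    (want_dir is None or slots[idx][1] == want_dir):
                available[idx] = False
                return idx
        return None

    groups: list[list[int]] = []
    coef_list: list[float] = []
    l_by_slot = np.empty(m)
    n_assigned = 0
    for _ in range(n_dup):
        if m - n_assigned < 2:
            break
        idx1 = _pop_next()
        ct1, d1 = slots[idx1]
        c = rng.standard_normal()
        l1, l2 = rho_gen * c + resid * rng.standard_normal(2)
        if math.copysign(1.0, l1) != d1:
            c, l1, l2 = -c, -l1, -l2
        s2 = int(math.copysign(1.0, l2))
        idx2 = _pop_matching(s2, ct1)
        if idx2 is None:
            idx2 = _pop_matching(None, ct1)
            if idx2 is None:  # no second cell type available: keep as single
                groups.append([idx1])
                coef_list.append(c)
                l_by_slot[idx1] = l1
                n_assigned += 1
                continue
            l2 = abs(l2) * slots[idx2][1]
        groups.append([idx1, idx2])
        coef_list.append(c)
        l_by_slot[idx1] = l1
        l_by_slot[idx2] = l2
        n_assigned += 2
    while n_assigned < m:
        idx = _pop_next()
        c = rng.standard_normal()
        l = rho_gen * c + resid * rng.standard_normal()
        if math.copysign(1.0, l) != slots[idx][1]:
            c, l = -c, -l
        groups.append([idx])
        coef_list.append(c)
        l_by_slot[idx] = l
        n_assigned += 1
    coef_by_group = np.array(coef_list)
    n_signal = len(groups)

    if n_signal + truth.n_peak_only_genes > n_genes:
        raise SimulationParameterError(
            f"n_genes={n_genes} too small for {n_signal} signal genes plus "
            f"{truth.n_peak_only_genes} peak-only genes")

    # --- gene universe assignment
    width = max(5, len(str(n_genes)))
    universe = [f"G{i:0{width}d}" for i in range(n_genes)]
    perm = rng.permutation(n_genes)
    signal_genes = [universe[i] for i in perm[:n_signal]]
    peak_only_genes = [universe[i] for i in perm[n_signal:n_signal + truth.n_peak_only_genes]]
    rest_genes = [universe[i] for i in perm[n_signal + truth.n_peak_only_genes:]]

    # --- concordance tuning by per-record Bernoulli coefficient flips
    f = truth.same_sign_frac_true
    if f is not None:
        f0 = 0.5 + math.asin(rho_gen) / math.pi
        if f > f0 and f0 < 1.0:
            q, fix_discordant = (f - f0) / (1.0 - f0), True
        elif f < f0 and f0 > 0.0:
            q, fix_discordant = (f0 - f) / f0, False
        else:
            q, fix_discordant = 0.0, True
        for gi, group in enumerate(groups):
            if q == 0.0:
                continue
            c = coef_by_group[gi]
            concord = [(c > 0) == (l_by_slot[idx] > 0) for idx in group]
            selected = [concord[j] != fix_discordant and rng.random() < q
                        for j in range(len(group))]
            if all(selected):
                coef_by_group[gi] = -c  # gene-level flip fixes every record
            else:
                for j, sel in enumerate(selected):
                    if sel:  # mixed multi-record gene: flip this record's log2fc
                        l_by_slot[group[j]] = -l_by_slot[group[j]]

    # --- materialize DEG records
    degs: list[DegRecord] = []
    for gi, group in enumerate(groups):
        for idx in group:
            ct, _ = slots[idx]
            degs.append(DegRecord(
                gene_symbol=signal_genes[gi], cell_type=ct,
                log2fc=float(l_by_slot[idx] * truth.log2fc_scale),
                adj_p=float(rng.uniform(1e-8, 0.0499))))

    # DEG-only records (no significant peak), one per gene
    w_down = truth.overall_frac_down
    ct_names = [ct for ct in CELL_TYPES if truth.celltype_degs.get(ct)
                and truth.celltype_degs[ct].n_records > 0]
    ct_weights = np.array([truth.celltype_degs[ct].n_records for ct in ct_names], dtype=float)
    ct_weights /= ct_weights.sum()
    n_deg_only = min(truth.n_deg_only_records, len(rest_genes))
    for gene in rest_genes[:n_deg_only]:
        ct = str(rng.choice(ct_names, p=ct_weights))
        mag = abs(rng.normal(0.0, truth.log2fc_scale)) + 1e-9
        sign = -1.0 if rng.random() < w_down else 1.0
        degs.append(DegRecord(gene_symbol=gene, cell_type=ct,
                              log2fc=float(sign * mag),
                              adj_p=float(rng.uniform(1e-8, 0.0499))))

    # --- materialize peaks
    state_p = (0.5, 0.3, 0.2)
    peaks: list[PeakRecord] = []
    counter = 0

    def _add_peak(gene: str, coef: float, fdr: float) -> None:
        nonlocal counter
        counter += 1
        chrom = f"chr{rng.integers(1, 23)}"
        start = int(rng.integers(10_000, 100_000_000))
        peaks.append(PeakRecord(
            peak_id=f"peak{counter:06d}", chrom=chrom, start=start,
            end=start + int(rng.integers(200, 2000)), gene_symbol=gene,
            chromatin_state=str(rng.choice(CHROMATIN_STATES, p=state_p)),
            coef_abeta=coef, fdr=fdr))

    for gi, gene in enumerate(signal_genes):
        coef = float(coef_by_group[gi] * truth.coef_scale)
        fdr = float(rng.uniform(1e-6, 0.0499))
        _add_peak(gene, coef, fdr)
        if rng.random() < truth.extra_peak_frac:
            # secondary peak: larger FDR, so min-FDR collapse keeps the truth coefficient
            _add_peak(gene, coef + float(rng.normal(0.0, 0.3 * truth.coef_scale)),
                      float(rng.uniform(fdr + 1e-9, 0.04999)))
    for gene in peak_only_genes:
        _add_peak(gene, float(rng.normal(0.0, truth.coef_scale)),
                  float(rng.uniform(1e-6, 0.0499)))
    for gene in rest_genes:
        _add_peak(gene, float(rng.normal(0.0, truth.coef_scale)),
                  float(rng.uniform(0.0501, 1.0)))

    peaks.sort(key=lambda p: (int(p.chrom[3:]), p.start, p.peak_id))
    degs.sort(key=lambda r: (CELL_TYPES.index(r.cell_type), r.gene_symbol))
    return peaks, degs


# ---------------------------------------------------------------------------
# Expression summaries


def _expression_table(rng: np.random.Generator, genes: list[str],
                      boost: Mapping[str, float] | None = None) -> pd.DataFrame:
    log_mean = rng.standard_normal(len(genes))
    if boost:
        for i, g in enumerate(genes):
            if g in boost:
                log_mean[i] += math.log(boost[g])
    mean_expr = np.exp(log_mean)
    frac = 1.0 / (1.0 + np.exp(-(log_mean + rng.normal(0.0, 0.5, len(genes)))))
    return pd.DataFrame({"mean_expr": mean_expr,
                         "frac_expressing": np.clip(frac, 1e-4, 1.0)},
                        index=pd.Index(genes, name="gene_symbol"))


def gen_fly_expression(truth: SimulationTruth, target_genes: Iterable[str],
                       n_background: int = 2000,
                       cell_types: tuple[str, ...] = DEFAULT_FLY_CELL_TYPES,
                       ) -> dict[str, CellTypeExpression]:
    """Fly per-cell-type expression with target genes over-expressed in
    perineurial glia by ``truth.enrichment_factor``.

    Expression is log-normal (strictly positive, right-skewed); the
    fraction-expressing column is a logistic transform of log expression
    plus noise, so highly expressed genes are detected in more cells.
    """
    target_genes = sorted(set(target_genes))
    if not target_genes:
        raise SimulationParameterError("target gene set must be non-empty")
    rng = _rng(truth.seed, "fly_expr")
    background = [f"CG{10000 + i}" for i in range(n_background)]
    genes = target_genes + [g for g in background if g not in set(target_genes)]
    out = {}
    boost = {g: truth.enrichment_factor for g in target_genes}
    for ct in cell_types:
        table = _expression_table(rng, genes,
                                  boost=boost if ct == "perineurial_glia" else None)
        out[ct] = CellTypeExpression(cell_type=ct, table=table)
    return out


def gen_human_expression(truth: SimulationTruth, genes: Iterable[str],
                         cell_types: tuple[str, ...] = CELL_TYPES,
                         ) -> dict[str, CellTypeExpression]:
    """Human per-cell-type expression summaries (log-normal, no built-in
    cross-species structure)."""
    genes = sorted(set(genes))
    if not genes:
        raise SimulationParameterError("gene set must be non-empty")
    rng = _rng(truth.seed, "human_expr")
    return {ct: CellTypeExpression(cell_type=ct, table=_expression_table(rng, genes))
            for ct in cell_types}


_SYNAPTIC_TERM_NAMES = (
    "synaptic vesicle cycle", "chemical synaptic transmission",
    "regulation of synaptic plasticity", "synaptic membrane adhesion",
    "presynaptic active zone organization", "postsynaptic density assembly",
    "synaptic signaling", "modulation of synaptic transmission",
)
_OTHER_TERM_NAMES = (
    "myelination", "chromatin organization", "axon guidance",
    "apoptotic process", "extracellular matrix organization",
    "oxidative phosphorylation", "RNA splicing", "dendrite morphogenesis",
    "glial cell differentiation", "lipid transport", "cilium assembly",
    "DNA repair", "protein folding", "cell adhesion", "ion transport",
    "immune response", "translation",
)


def gen_go_annotations(truth: SimulationTruth, genes: Iterable[str],
                       n_terms: int = 25, term_size: tuple[int, int] = (10, 40),
                       ) -> list[GoAnnotation]:
    """A small GO-style annotation: ~1/3 of terms carry the keyword
    "synaptic" in their name; gene sets are random subsets of ``genes``."""
    genes = sorted(set(genes))
    if not genes:
        raise SimulationParameterError("gene universe must be non-empty")
    rng = _rng(truth.seed, "go")
    names = list(_SYNAPTIC_TERM_NAMES) + list(_OTHER_TERM_NAMES)
    out = []
    for i in range(n_terms):
        name = names[i % len(names)]
        size = min(int(rng.integers(term_size[0], term_size[1] + 1)), len(genes))
        members = rng.choice(genes, size=size, replace=False)
        out.append(GoAnnotation(term_id=f"GO:S{i:05d}", term_name=name,
                                genes=frozenset(str(g) for g in members)))
    return out


# ---------------------------------------------------------------------------
# Homologue map


def gen_homolog_map(human_genes: Iterable[str], coverage: float,
                    seed: int) -> list[HomologPair]:
    """Map exactly round(coverage * n) human genes to one fly homologue each."""
    if not 0.0 <= coverage <= 1.0:
        raise SimulationParameterError(f"coverage must be in [0, 1], got {coverage}")
    human_genes = sorted(set(human_genes))
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS["homologs"],)))
    n_map = round(coverage * len(human_genes))
    chosen = sorted(str(g) for g in rng.choice(human_genes, size=n_map, replace=False)) \
        if n_map else []
    return [HomologPair(human_gene=g, fly_gene=f"d{g.capitalize()}",
                        confidence=float(rng.uniform(0.5, 1.0))) for g in chosen]


# ---------------------------------------------------------------------------
# Electrophysiology


def _positive_normal(rng: np.random.Generator, mean: float, sd: float,
                     size: int) -> np.ndarray:
    """Normal draws truncated at zero (resampled), keeping amplitudes positive."""
    x = rng.normal(mean, sd, size)
    while True:
        bad = x <= 0
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, int(bad.sum()))


def gen_ephys_cohort(truth: SimulationTruth,
                     n_cells_per_group: int = 12) -> list[EphysCell]:
    """Per-cell mEPSP/EPSP cohort for every genotype in the truth.

    Baseline (-PhTX) cells draw quantal size around ``mepsp0_mv`` and
    quantal content around ``qc0``.  PhTX multiplies the mean quantal size
    by ``phtx_effect``; the genotype's homeostatic gain scales the
    compensatory rise in quantal content so that the expected QC ratio is
    1 + gain * (1/phtx_effect - 1).  EPSP is the product of the cell's
    quantal size and content.
    """
    if n_cells_per_group < 3:
        raise SimulationParameterError(
            f"n_cells_per_group must be >= 3, got {n_cells_per_group}")
    rng = _rng(truth.seed, "ephys")
    cv = truth.ephys_cv
    cells = []
    for genotype, gain in truth.genotype_gains.items():
        qc_plus_mean = truth.qc0 * (1.0 + gain * (1.0 / truth.phtx_effect - 1.0))
        for phtx, mepsp_mean, qc_mean in (
                ("absent", truth.mepsp0_mv, truth.qc0),
                ("present", truth.mepsp0_mv * truth.phtx_effect, qc_plus_mean)):
            mepsp = _positive_normal(rng, mepsp_mean, cv * mepsp_mean, n_cells_per_group)
            qc = _positive_normal(rng, qc_mean, cv * qc_mean, n_cells_per_group)
            cells.extend(EphysCell(genotype=genotype, phtx=phtx,
                                   mepsp_mv=float(a), epsp_mv=float(a * q))
                         for a, q in zip(mepsp, qc))
    return cells


def gen_genotype_annotations(truth: SimulationTruth) -> pd.DataFrame:
    """Per-genotype human-gene dysregulation magnitudes.

    Encodes the ground-truth coupling the ephys correlation stage is meant
    to recover: genotypes with weaker homeostatic gain correspond to human
    genes with larger |log2fc| and |coef_abeta|.  The wild type carries no
    gene annotation and is excluded.
    """
    rng = _rng(truth.seed, "annotations")
    rows = []
    for genotype, gain in truth.genotype_gains.items():
        if genotype == "wt":
            continue
        rows.append({
            "genotype": genotype,
            "abs_log2fc": float(np.clip(0.15 + 0.55 * (1.0 - gain)
                                        + rng.normal(0.0, 0.05), 0.01, None)),
            "abs_coef_abeta": float(np.clip(0.08 + 0.35 * (1.0 - gain)
                                            + rng.normal(0.0, 0.04), 0.005, None)),
        })
    return pd.DataFrame(rows, columns=["genotype", "abs_log2fc", "abs_coef_abeta"])


# ---------------------------------------------------------------------------
# Full input bundle


def generate_bundle(truth: SimulationTruth, n_genes: int = 2000,
                    n_cells_per_group: int = 12, homolog_coverage: float = 0.85,
                    n_fly_background: int = 2000) -> dict:
    """Generate every pipeline input as one consistent bundle.

    The fly enrichment target set is derived the same way the analysis
    consumes it — the fly homologues of the top-20 "synaptic" astrocyte
    genes — so the perineurial-glia enrichment encoded by
    ``truth.enrichment_factor`` is realized for the gene set the pipeline
    will actually test.
    """
    from .xspecies import resolve_homologs, select_synaptic_genes, top_n_expressed

    peaks, degs = gen_peak_deg_tables(truth, n_genes=n_genes)
    human_genes = sorted({d.gene_symbol for d in degs} | {p.gene_symbol for p in peaks})
    homologs = gen_homolog_map(human_genes, coverage=homolog_coverage, seed=truth.seed)
    go = gen_go_annotations(truth, human_genes)
    human_expr = gen_human_expression(truth, human_genes)

    synaptic = select_synaptic_genes(go)
    fly_map = resolve_homologs(homologs)
    targets = set()
    for ct in human_expr:
        top = top_n_expressed(human_expr[ct], synaptic, n=20)
        targets |= {fly_map[g] for g in top if g in fly_map}
    if not targets:  # degenerate annotation; fall back to any mapped genes
        targets = set(list(fly_map.values())[:20])
    fly_expr = gen_fly_expression(truth, targets, n_background=n_fly_background)

    return {
        "truth": truth,
        "peaks": peaks,
        "degs": degs,
        "homologs": homologs,
        "go": go,
        "human_expression": human_expr,
        "fly_expression": fly_expr,
        "ephys": gen_ephys_cohort(truth, n_cells_per_group=n_cells_per_group),
        "annotations": gen_genotype_annotations(truth),
    }


def truth_to_dict(truth: SimulationTruth) -> dict:
    d = dataclasses.asdict(truth)
    d["celltype_degs"] = {ct: dataclasses.asdict(p)
                          for ct, p in truth.celltype_degs.items()}
    d["genotype_gains"] = dict(truth.genotype_gains)
    return d


def truth_from_dict(d: Mapping) -> SimulationTruth:
    d = dict(d)
    if "celltype_degs" in d:
        d["celltype_degs"] = {ct: CellTypeDegProfile(**p)
                              for ct, p in d["celltype_degs"].items()}
    return SimulationTruth(**d)


def write_bundle(bundle: Mapping, outdir) -> dict[str, str]:
    """Write every bundle table as TSV plus a ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peaks": outdir / "peaks.tsv",
        "degs": outdir / "degs.tsv",
        "homologs": outdir / "homologs.tsv",
        "go": outdir / "go_annotation.tsv",
        "human_expression": outdir / "human_expression.tsv",
        "fly_expression": outdir / "fly_expression.tsv",
        "ephys": outdir / "ephys.tsv",
    }
    sio.write_peaks(bundle["peaks"], paths["peaks"])
    sio.write_degs(bundle["degs"], paths["degs"])
    sio.write_homologs(bundle["homologs"], paths["homologs"])
    sio.write_go(bundle["go"], paths["go"])
    sio.write_expression(bundle["human_expression"], paths["human_expression"])
    sio.write_expression(bundle["fly_expression"], paths["fly_expression"])
    sio.write_ephys(bundle["ephys"], paths["ephys"])
    ann_path = outdir / "genotype_annotations.tsv"
    bundle["annotations"].to_csv(ann_path, sep="\t", index=False,
                                 float_format="%.12g")
    paths["annotations"] = ann_path
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth_to_dict(bundle["truth"]), fh, indent=2, sort_keys=True)
    paths["truth"] = truth_path
    return {k: str(v) for k, v in paths.items()}
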