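"""Quantal analysis of presynaptic homeostatic potentiation (PHP).

Quantal content (QC) — the EPSP amplitude divided by the mEPSP amplitude —
estimates the number of vesicles released per action potential.  PHP is
called intact for a genotype when philanthotoxin (PhTX) application raises
QC significantly: the compensatory increase in release that keeps the
evoked potential at its baseline amplitude despite the reduced quantal
size.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import correlation
from .records import EphysCell, GenotypeSummary

__all__ = [
    "quantal_content",
    "summarize_genotype",
    "summarize_cohort",
    "estimate_gain",
    "php_dysregulation_corr",
]


def quantal_content(epsp_mv: float, mepsp_mv: float) -> float:
    """EPSP amplitude over mEPSP amplitude; requires a positive mEPSP."""
    if not mepsp_mv > 0:
        raise ValueError(f"mEPSP amplitude must be > 0 mV, got {mepsp_mv}")
    return epsp_mv / mepsp_mv


def summarize_genotype(cells: Iterable[EphysCell], genotype: str,
                       ttest: str = "welch", alpha: float = 0.05) -> GenotypeSummary:
    """Per-genotype PHP metrics from per-cell recordings.

    QC is computed per cell first, then averaged per PhTX condition.
    Percentages are ratios of group means (+PhTX over -PhTX baseline),
    x100.  ``qc_p`` is the two-sided t-test on per-cell QC between
    conditions — Welch (unequal variance) by default, ``ttest="student"``
    for the pooled-variance variant.  ``php_intact`` requires both
    significance at ``alpha`` and an increase in mean QC.
    """
    if ttest not in ("welch", "student"):
        raise ValueError(f"unknown ttest variant {ttest!r}")
    mine = [c for c in cells if c.genotype == genotype]
    minus = [c for c in mine if c.phtx == "absent"]
    plus = [c for c in mine if c.phtx == "present"]
    if not minus or not plus:
        missing = "-PhTX" if not minus else "+PhTX"
        raise ValueError(f"genotype {genotype!r}: no cells recorded in the "
                         f"{missing} condition")

    def _means(group):
        mepsp = np.array([c.mepsp_mv for c in group])
        epsp = np.array([c.epsp_mv for c in group])
        qc = np.array([quantal_content(c.epsp_mv, c.mepsp_mv) for c in group])
        return mepsp, epsp, qc

    mepsp_m, epsp_m, qc_m = _means(minus)
    mepsp_p, epsp_p, qc_p_vals = _means(plus)
    if len(qc_m) >= 2 and len(qc_p_vals) >= 2:
        test = stats.ttest_ind(qc_p_vals, qc_m, equal_var=(ttest == "student"))
        p_value = float(test.pvalue)
    else:
        p_value = math.nan  # t-test needs >= 2 cells per condition
    mean_qc_minus, mean_qc_plus = float(qc_m.mean()), float(qc_p_vals.mean())
    return GenotypeSummary(
        genotype=genotype, n_minus=len(minus), n_plus=len(plus),
        mean_mepsp_minus=float(mepsp_m.mean()), mean_mepsp_plus=float(mepsp_p.mean()),
        mean_epsp_minus=float(epsp_m.mean()), mean_epsp_plus=float(epsp_p.mean()),
        mean_qc_minus=mean_qc_minus, mean_qc_plus=mean_qc_plus,
        pct_mepsp=100.0 * float(mepsp_p.mean()) / float(mepsp_m.mean()),
        pct_epsp=100.0 * float(epsp_p.mean()) / float(epsp_m.mean()),
        pct_qc=100.0 * mean_qc_plus / mean_qc_minus,
        qc_p=p_value,
        php_intact=bool(not math.isnan(p_value) and p_value < alpha
                        and mean_qc_plus > mean_qc_minus))


def summarize_cohort(cells: Iterable[EphysCell], ttest: str = "welch",
                     alpha: float = 0.05) -> list[GenotypeSummary]:
    """Summaries for every genotype, in order of first appearance."""
    cells = list(cells)
    genotypes = list(dict.fromkeys(c.genotype for c in cells))
    return [summarize_genotype(cells, g, ttest=ttest, alpha=alpha) for g in genotypes]


def estimate_gain(summary: GenotypeSummary, phtx_effect: float) -> float:
    """Homeostatic gain implied by the QC ratio.

    Inverts the compensation model QC(+)/QC(-) = 1 + gain*(1/phtx_effect - 1):
    0 means no compensation, 1 full compensation of the quantal-size loss.
    """
    if not 0.0 < phtx_effect < 1.0:
        raise ValueError(f"phtx_effect must be in (0, 1), got {phtx_effect}")
    return (summary.pct_qc / 100.0 - 1.0) / (1.0 / phtx_effect - 1.0)


def php_dysregulation_corr(summaries: Iterable[GenotypeSummary],
                           gene_annotations: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations between PHP impairment and AD dysregulation.

    ``gene_annotations`` carries, per genotype, the |log2fc| and
    |coef_abeta| of the corresponding human gene.  Returns one row per
    correlation: %EPSP vs |log2fc|, %QC vs |log2fc|, %QC vs |coef_abeta|,
    and baseline QC vs |coef_abeta| (each with a two-sided p), over the
    genotypes present in both inputs (>= 3 required).
    """
    required = {"genotype", "abs_log2fc", "abs_coef_abeta"}
    missing = required - set(gene_annotations.columns)
    if missing:
        raise ValueError(f"gene_annotations missing column(s): {sorted(missing)}")
    by_genotype = {s.genotype: s for s in summaries}
    ann = gene_annotations[gene_annotations["genotype"].isin(by_genotype)]
    if len(ann) < 3:
        raise ValueError(f"need >= 3 annotated genotypes with ephys summaries, "
                         f"got {len(ann)}")
    pct_epsp = np.array([by_genotype[g].pct_epsp for g in ann["genotype"]])
    pct_qc = np.array([by_genotype[g].pct_qc for g in ann["genotype"]])
    qc_baseline = np.array([by_genotype[g].mean_qc_minus for g in ann["genotype"]])
    abs_l2fc = ann["abs_log2fc"].to_numpy(dtype=float)
    abs_coef = ann["abs_coef_abeta"].to_numpy(dtype=float)
    pairs = [
        ("pct_epsp", "abs_log2fc", pct_epsp, abs_l2fc),
        ("pct_qc", "abs_log2fc", pct_qc, abs_l2fc),
        ("pct_qc", "abs_coef_abeta", pct_qc, abs_coef),
        ("baseline_qc", "abs_coef_abeta", qc_baseline, abs_coef),
    ]
    rows = []
    for name_x, name_y, x, y in pairs:
        r, p = correlation(x, y, method="spearman")
        rows.append({"metric": name_x, "versus": name_y, "spearman_r": r,
                     "p": p, "n_genotypes": len(x)})
    return pd.DataFrame(rows)
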