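"""Quantal analysis of presynaptic homeostatic potentiation (PHP).

Philanthotoxin halves the quantal size (mEPSP).  A genotype with intact
PHP raises its quantal content (QC = EPSP/mEPSP) enough to keep the
evoked potential at baseline; blocked genotypes do not.  PHP impairment
is then correlated, across genotypes, with how strongly the homologous
human gene is dysregulated in AD.
"""

from synacet import SimulationTruth, gen_ephys_cohort
from synacet.ephys import estimate_gain, php_dysregulation_corr, summarize_cohort
from synacet.simulate import gen_genotype_annotations

truth = SimulationTruth(seed=42)
cells = gen_ephys_cohort(truth, n_cells_per_group=12)
summaries = summarize_cohort(cells)

print(f"{'genotype':20s} {'%mEPSP':>7s} {'%EPSP':>7s} {'%QC':>7s} "
      f"{'QC p':>9s}  intact  gain_hat")
for s in summaries:
    gain = estimate_gain(s, truth.phtx_effect)
    print(f"{s.genotype:20s} {s.pct_mepsp:7.1f} {s.pct_epsp:7.1f} "
          f"{s.pct_qc:7.1f} {s.qc_p:9.2g}  {str(s.php_intact):6s}  {gain:5.2f}")

corr = php_dysregulation_corr(summaries, gen_genotype_annotations(truth))
print()
print(corr.round(3).to_string(index=False))
# %EPSP near 100 with %QC near 200 marks full homeostatic compensation
# (the wild type); mutants sit near %EPSP 50 / %QC 100.  The negative
# Spearman between %EPSP and |log2fc| says genotypes whose human genes
# are more dysregulated in AD show stronger PHP impairment.
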