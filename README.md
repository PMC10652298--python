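# synacet

Integrative analysis linking amyloid-associated histone-acetylation
(H3K9ac) dysregulation to cell-type-specific transcriptomic change in
Alzheimer's disease (AD), and linking both to presynaptic homeostatic
potentiation (PHP) at the *Drosophila* neuromuscular junction.

The package is aimed at groups who have (or can summarize) three kinds of
data — an H3K9ac ChIP-seq peak table with per-peak amyloid regression
coefficients, a cell-type-resolved differential-expression (DEG) table
from snRNA-seq, and per-cell mEPSP/EPSP recordings by genotype and
philanthotoxin (PhTX) condition — and want the full statistical chain
between them, plus a synthetic-data generator with controllable ground
truth so every stage is testable without any download.

## What it computes

**Epigenome–transcriptome integration.** Peaks with amyloid-association
FDR < 0.05 are collapsed to genes (minimum-FDR peak wins) and joined with
DEG records; the unit of analysis is the gene × cell type pair. Each
multi-cell-type gene is assigned a primary cell type by largest |log2FC|.

**Sign concordance.** A record is *same sign* when its amyloid coefficient
β(Aβ) on H3K9ac and its transcriptional log2 fold change satisfy
sign(β) = sign(log2FC). With k concordant records of n, the exact
two-sided binomial test evaluates

  p = Σ_{j : P(X=j) ≤ P(X=k)} P(X = j),  X ~ Binomial(n, ½),

alongside Pearson r between β(Aβ) and log2FC, pooled and per cell type.
A generic hypergeometric over-representation utility (BH-adjusted) covers
GO screening of the amyloid-target gene set.

**Cross-species enrichment.** "Synaptic" genes (GO term names containing
the keyword) are ranked by human per-cell-type expression; the top 20 are
mapped to fly homologues and their mean perineurial-glia expression is
compared with 10,000 random same-size subsets of expressed genes — the
reported percentile is the fraction of null draws strictly below the
observed mean. Spearman correlations compare human expression with fly
homologue expression (or fraction of cells expressing).

**Quantal PHP analysis.** Quantal content QC = EPSP/mEPSP per cell;
per genotype, %mEPSP, %EPSP and %QC are ratios of +PhTX to −PhTX group
means (×100); PHP is called intact when a two-sided Welch t-test on
per-cell QC is significant *and* QC increases. The homeostatic gain
γ = (%QC/100 − 1)/(1/e − 1), where e is the PhTX quantal-size multiplier,
estimates the compensated fraction (γ=1 full compensation, γ=0 blocked).
Spearman correlations relate %EPSP and %QC to the |log2FC| and |β(Aβ)| of
each genotype's human gene.

**Synthetic ground truth.** One seed drives every generator: a Gaussian
copula (correlation calibrated analytically so the pooled Pearson equals
the requested ρ after direction folding) with Bernoulli sign flips tuned
to the requested concordance fraction; log-normal expression with a
configurable perineurial-glia enrichment factor; truncated-normal
amplitude noise with per-genotype gains.

## Worked example

```sh
python examples/03_concordance.py
```

```
scope   n  k_same_sign  pct_same_sign  binom_p  pearson_r  pearson_p
  all 100           75        75.0000   0.0000     0.4276     0.0000
   Ex  35           26        74.2857   0.0060     0.3786     0.0249
  ...
75/100 records concordant (75%), exact binomial p = 5.6e-07; Pearson r = 0.43
```

On this simulated dataset (ground truth: ρ = 0.37, concordance 0.69),
75 of the 100 integrated records are sign-concordant — far from the 50%
expected under independent signs (exact binomial p ≈ 6e-7) — and the
positive Pearson r says stronger amyloid effects on acetylation go with
stronger same-direction expression shifts. `examples/05_quantal_php.py`
prints the matching electrophysiology table: the wild type holds %EPSP
near 100 by doubling QC under PhTX, mutants sit near %EPSP 50 with flat
QC, and %EPSP correlates negatively (Spearman ≈ −0.8 there) with the
human genes' |log2FC|.

Other entry points: `examples/01…06` cover each capability; the `synacet`
CLI exposes `simulate / integrate / concordance / xspecies / quantal /
run / report` subcommands; `synacet run --out DIR` executes the bundled
demo config end-to-end and is byte-reproducible.

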