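# Methods

## The analysis chain

The pipeline treats three measurement layers of the same biological
process — amyloid-β pathology altering H3K9ac, H3K9ac altering
transcription, and transcriptional dysregulation of glial genes degrading
homeostatic synaptic plasticity — as a chain of testable statistical
couplings.

1. **Peak filtering and gene collapse.** An H3K9ac peak is
   amyloid-associated when its regression FDR is strictly below 0.05 (the
   cut is deliberately strict, not ≤). When several peaks annotate one
   gene, the peak with the smallest FDR supplies the gene's amyloid
   coefficient and chromatin state; FDR ties fall back to largest
   |coefficient|, then input order. Nothing in the deposited-data
   conventions fixes this collapse rule, so it is explicit and the
   selection function is small enough to swap.
2. **Integration.** The unit of analysis is the (gene, cell type) record:
   a gene differentially expressed in two cell types contributes two
   records sharing one amyloid coefficient. This is what makes "100
   records over 87 genes" a natural pair of counts rather than a
   bookkeeping artifact. Primary-cell-type assignment (largest |log2FC|)
   breaks exact ties by the fixed order Ex, In, Ast, Oli, OPC, Mic so the
   result is independent of row order.
3. **Concordance.** Records with either signal exactly zero have no
   defined direction and are excluded from both numerator and denominator
   (and from the correlations). The two-sided binomial test uses the
   minimum-likelihood convention — sum of all outcome probabilities not
   exceeding the observed one, with a 1e-7 relative guard for
   floating-point ties between pmf(k) and pmf(n−k); a central
   (doubled-tail) variant is available by flag. No multiple-testing
   correction is applied across the per-cell-type tests by default; the
   hypergeometric utility reports BH-adjusted values because GO screens
   test many terms.
4. **Cross-species enrichment.** The bootstrap statistic is the plain
   mean of perineurial-glia mean expression over the target homologues;
   the null resamples same-size gene sets without replacement from the
   expressed universe (fraction-expressing > 0.01 by default, an
   adjustable convention). An EWCE-style specificity transform
   (expression divided by its sum across fly cell types) is available via
   `specificity_of=`; the percentile uses strict inequality, so ties with
   the observed statistic count against enrichment. One-to-many homologue
   relations resolve by highest confidence, then alphabetically.
5. **Quantal PHP.** QC is computed per cell before any averaging (QC is
   scale-invariant per cell; means of ratios and ratios of means differ).
   Percentage metrics are ratios of group means, which is the reading of
   "percentage of the same genotype without PhTX" that is robust to
   single-cell outliers; a mean-of-ratios variant would be a one-line
   change but is not exposed. The QC test is Welch's by default —
   "Student's t-test" in the source analysis does not state equal
   variances, and group sizes there are very unbalanced — with the
   pooled-variance variant behind `ttest="student"`. `php_intact`
   requires significance *and* a QC increase, since PHP is by definition
   a compensatory increase in release.

## Synthetic ground truth

The generator produces all six input tables from one
`SimulationTruth` and one seed; per-generator substreams come from
`SeedSequence(seed, spawn_key=(stream,))`, so tables are individually and
jointly reproducible.

**Peak/DEG copula.** Per gene, (coefficient, log2FC) is bivariate normal
with copula correlation ρ_gen, then scaled (0.4 and 0.5 respectively —
magnitudes in the range typical of such regression coefficients and
single-cell log fold changes). Regulation direction is imposed per cell
type with *exact* down-regulated counts by folding the pair into the
demanded half-plane (joint negation). Folding with an unbalanced up/down
mix attenuates the pooled Pearson correlation by the closed-form factor
√((1−d)/(1−ρ²d)), d = (1−2w)²·2/π with w the overall down fraction, so
ρ_gen is pre-solved so the *post-folding* population correlation equals
the requested `rho_true`. Genes carrying a second cell type share their
coefficient; the second record's value is left untouched and is instead
assigned to an open direction slot matching its realized sign, which
keeps exact counts without distorting the joint law (a residual bias
below 0.005 in pooled r remains from these records' slightly different
folded component, measured but not corrected).

**Concordance tuning.** Under the copula a record is concordant with
probability f₀ = ½ + arcsin(ρ_gen)/π. To reach a target fraction f,
discordant records flip their coefficient's sign independently with
probability (f−f₀)/(1−f₀) (symmetrically for f < f₀). Per-record
independence keeps the concordant count Binomial(n, f) — the property the
type-I-error calibration rests on. `same_sign_frac_true=None` disables
tuning. Combinations whose concordance target opposes the correlation's
sign are refused (`SimulationParameterError`): reaching them would
require flips that destroy the requested correlation. Defaults
(ρ = 0.37, f = 0.69) mirror the integration analysis's reported pooled
values; because tuning flips are conditional on discordance, the realized
Pearson r under these defaults sits somewhat above 0.37.

**Expression.** Log-normal mean expression (log-SD 1) with
fraction-expressing a noisy logistic of log expression, so abundant genes
are detected in more cells; everything is strictly positive and
right-skewed like depth-normalized expression summaries. The enrichment
factor multiplies target-gene expression only in perineurial glia.

**Electrophysiology.** Baselines mEPSP₀ = 0.8 mV and QC₀ = 45 (evoked
amplitude ≈ 36 mV) are typical wild-type NMJ values; PhTX multiplies the
mean quantal size by `phtx_effect` = 0.5 (the canonical "roughly halves
mEPSP" dose). The expected QC ratio is 1 + γ(1/e − 1); γ = 1 restores
%EPSP = 100, γ = 0 leaves %EPSP = 100·e. Amplitude noise is normal with
CV 0.15, resampled at zero so amplitudes stay positive. Default genotype
gains encode the screen's phenotype: wild type 1.0, nine loss-of-function
mutants 0.0–0.1 (PHP blocked), motoneuron knockdowns 0.55–0.9 (partial).
Genotype annotations couple |log2FC| and |coefficient| inversely to gain
with small noise, the structure the correlation stage is meant to
recover.

**What the generator does not emulate.** Read-level data, per-cell count
matrices and voltage traces; LD-like correlation between peaks; shared
noise between human cell types; any real homologue structure (maps are
synthetic 1:1); GO term content (names are labels around the "synaptic"
keyword). Passing tests therefore demonstrate the statistical machinery
is correct and calibrated under a controlled data-generating process,
not that the biological conclusions transfer to any particular deposited
dataset.

## Numerical and sizing choices

- Binomial pmf comparisons use a 1e-7 relative tolerance; adjacent
  binomial coefficients at n ≤ 200 differ by ≥ ~1%, so only exact ties
  are absorbed.
- Floats serialize at 12 significant digits; round-trips are exact to
  that precision. Undefined same-sign flags serialize as the literal
  token `NA`; blank numeric cells are an error, never silently missing.
- Bootstrap subsampling vectorizes via argpartition of random keys in
  row chunks capped near 2·10⁷ key draws, bounding memory while keeping
  10,000 draws fast; the percentile's Monte-Carlo SE at n_boot = 10⁴ is
  ≤ 0.5 points.
- Correlations require ≥ 3 points and non-constant inputs; smaller or
  degenerate scopes report counts with the correlation undefined rather
  than failing the run.
- Calibration-style tests use deliberately lean problem sizes — e.g.
  2000 null datasets of 100 records over a 120-gene universe, 100 seeds
  at 5000 records for correlation recovery, 400–500 bootstrap draws per
  seed for percentile calibration, 100 cells/group for gain recovery —
  chosen so each property is measured with comfortable statistical margin
  while the whole suite stays quick on a single CPU.

## Known limitations

- The exact binomial test is discrete: at n = 100 its true size at
  α = 0.05 is 0.0352, not 0.05. The test is correctly calibrated in the
  sense that its size matches the analytic value (asserted in the unit
  suite); no continuity correction is applied.
- The `php_intact` call inherits a ~2.5% directional false-positive rate
  at γ = 0 from the two-sided test at α = 0.05; genotype screens needing
  tighter control should lower `alpha`.
- Heavy concordance tuning (|f − f₀| large) visibly perturbs the realized
  correlation away from `rho_true`; parameter-recovery studies of ρ
  should disable tuning.
- The pipeline consumes summary tables only; peak calling, the amyloid
  regression itself, snRNA-seq clustering/DE and trace event detection
  are upstream of its scope.
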