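# Methods

## The model

Two-sample MR treats each harmonized instrument j as an independent natural
experiment. Writing γⱼ for the true SNP-exposure effect and Γⱼ for the true
SNP-outcome effect (log-odds), the structural model is

    Γⱼ = θ·γⱼ + αⱼ

with θ the causal log-odds ratio per unit exposure and αⱼ a direct
(horizontally pleiotropic) effect that is zero for a valid instrument. The
observed summary statistics are γ̂ⱼ ~ N(γⱼ, se²_γⱼ) and Γ̂ⱼ ~ N(Γⱼ, se²_Γⱼ),
independent across j (instruments are LD-clumped) and between samples (the
exposure and outcome GWAS share no participants).

Validity rests on the three instrumental-variable assumptions: association
with the exposure (enforced by the p < 1e-5 selection and the F ≥ 10 strength
filter), independence from confounders (approximated by removing variants
annotated to confounder traits such as smoking), and exclusion restriction
(approximated by removing outcome-associated variants, and probed after the
fact by the Egger intercept, MR-PRESSO and heterogeneity statistics).

## Estimator conventions

The field's reference implementations differ quietly on several numerical
conventions; the ones adopted here are:

- **Wald ratio SE** is first-order: se(β̂ⱼ) = se_Γⱼ/|γ̂ⱼ|, ignoring exposure
  uncertainty. This is the standard default in two-sample MR tooling.
- **Random effects** are multiplicative: the fixed-effect SE is inflated by
  √φ with φ = max(1, Q/df), so heterogeneity can widen but never narrow
  intervals. Q is Cochran's Q for IVW (df = J−1) and Rucker's Q′ for Egger
  (df = J−2).
- **Reference distributions**: two-sided normal p-values for IVW and the
  weighted median; two-sided t(J−2) for both Egger coefficients.
- **Egger orientation**: instruments are flipped so γ̂ⱼ ≥ 0 before the Egger
  fit only — the intercept is orientation-dependent, whereas ratio-based
  estimators are not (a property the tests assert).
- **Weighted median**: inverse-variance weights wⱼ = γ̂ⱼ²/se²_Γⱼ normalized
  to 1; the estimate is the linear interpolation of ordered ratios against
  cumulative-midpoint weights at 0.5 (clamped to the extreme ratios if the
  crossing falls outside). The SE is the standard deviation of the estimator
  over a seeded parametric bootstrap (default 1,000 replicates); the seed is
  mandatory, so identical inputs give identical output.
- **MR-PRESSO** follows the residual-sum-and-outlier formulation: observed
  weighted residuals against leave-one-out IVW predictions; a parametric
  null resample of size K (default 1,000); empirical p-values via the
  add-one rule (#exceedances+1)/(K+1), hence never 0 and bounded below by
  1/(K+1); per-SNP p-values Bonferroni-multiplied by J and capped at 1; the
  outlier-corrected estimate is exactly `ivw` on the non-outlier subset, and
  the distortion statistic is the percent change of the IVW slope against
  removal of random same-size subsets. With J < 4 the leave-one-out slope is
  under-determined and the test reports itself inapplicable (matching the NA
  entries published tools print for 3-SNP exposures); an absent PRESSO
  result counts as non-significant downstream, never as significant.
  The "raw" PRESSO estimate is defined as the full-set IVW estimate, so the
  MR-PRESSO p feeding the tier rules equals the IVW p when no outliers are
  removed and the corrected IVW p otherwise.
- **Confidence intervals** on the odds-ratio scale use exp(β̂ ± 1.959964·se);
  the constant is fixed at six decimals for bit-stable outputs.
- p-values are clamped below at the smallest positive double, keeping them in
  (0, 1] even for extreme z.

## Tier classification

Level-specific Bonferroni thresholds are 0.05/n with n the number of taxa
tested at that taxonomic level (defaults 9/16/20/32/119 for
phylum/class/order/family/genus — panel sizes after removing unclassified
groups). Only the IVW p enters the Bonferroni comparison: requiring all three
main analyses to survive correction would be inconsistent with published
classifications in which a taxon is highly probable while its weighted-median
p is above 0.05. The *probable* tier requires all three main analyses
(IVW, WM, MR-PRESSO) present and nominally significant; *possible* requires
at least one. Exclusions strike a classified taxon to *none* when the Egger
intercept or PRESSO global p is below 0.05 (pleiotropy), either Q p is below
0.05 (heterogeneity), or any leave-one-out refit flips the sign of the full
estimate or destroys its nominal significance (the published criterion
"inconsistent leave-one-out results" is not operationalized anywhere, so this
sign-or-significance rule is this package's definition; only IVW refits are
considered).

## The synthetic-data generator

`simulate_pair` emulates the two-sample design the pipeline targets: a
quantitative microbial-abundance exposure from one cohort (default
n = 18,340) and a binary outcome from an independent case-control
meta-analysis (defaults 54,606 cases / 887,000 controls). Standard errors
use the 1/√(2·maf(1−maf)·n) approximation, with the effective sample size
n_case·n_control/(n_case+n_control) for the binary trait, so per-variant
genotypes are never simulated. Minor-allele frequencies are uniform on
(0.05, 0.5).

True exposure effects are scaled-normal draws oriented positive,
γⱼ = se_γⱼ·|N(0, k²)| with instrument strength k = 7 by default: the
expected F statistic (≈ k² + 1 ≈ 50) sits comfortably above the
suggestive-selection regime (p < 1e-5 ↔ F ≈ 20), and the between-SNP spread
of γ keeps the no-measurement-error condition of MR-Egger approximately
satisfied (I²_GX ≈ 95%). Orienting the effect allele to increase the
exposure is what makes "directional" pleiotropy well defined: a symmetric γ
draw would randomize instrument orientation and average any directional
direct effect to zero under Egger's γ ≥ 0 convention. Invalid instruments
(a fraction π, rounded to a count) receive αⱼ ~ N(μ, σ²_pleio), correlated
0.8 with γⱼ when the InSIDE-violation flag is set. Planted outliers shift
Γ̂ⱼ by a configured multiple of se_Γⱼ. A configurable fraction of variants
gets palindromic allele pairs; LD is exchangeable r² within consecutive
blocks and zero across blocks, with blocks placed further apart than any
clumping window. Panels derive one seed per taxon from the master seed plus
a CRC-32 of the taxon name, so panel content is independent of generation
order.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: LD is supplied as exact pairwise r² rather than
estimated from a reference panel; allele frequencies match perfectly between
samples; effect-size distributions are not taxon-specific (no compositional
structure, no winner's-curse from discovery selection); and sample overlap
between exposure and outcome GWAS is exactly zero.

## Calibration properties and problem sizes

The test suite verifies, at the sizes given: type-I error of IVW and
Cochran's Q within [0.03, 0.07] at the 0.05 level (1,000 replicates, J = 50,
θ = 0); PRESSO global rejection within [0.02, 0.09] (500 replicates,
K = 500); IVW 95% CI coverage within [0.92, 0.98] and mean bias below 0.02
at θ = ln 1.2 (500 replicates); detection of a planted 10σ outlier among 20
clean instruments in ≥ 95% of 100 replicates; and, under 40% directional
pleiotropy, a smaller weighted-median than IVW bias and recovery of the mean
direct effect by the Egger intercept. These sizes were chosen to make the
Monte-Carlo error small relative to the tested bands while keeping the
default suite quick to run.

One estimator property deserves explicit statement: the Egger intercept is a
weighted errors-in-variables regression coefficient, so at any finite
instrument strength it carries an O(1/k²) regression-dilution bias relative
to the average direct effect (measured ≈ −18% of the target at k = 7, i.e.
≈ 0.002 on a target of π·μ = 0.012). The recovery tests therefore allow a
25% dilution margin on top of Monte-Carlo error; the bias shrinks as
instrument strength grows and is a property of the estimator, not of this
implementation. Relatedly, with 40% invalid instruments the intercept
targets the mean direct effect across *all* instruments (π·μ), not the mean
among invalid ones (μ).

## Degenerate inputs and tie-breaks

- Clumping breaks p-value ties by (chrom, pos), then rsid, for determinism;
  variants are discarded at r² ≥ the threshold (boundary inclusive).
- Selection is strictly p < threshold (a p exactly at 1e-5 is excluded).
- `ivw` with a single instrument reduces exactly to the Wald ratio; with
  none it raises. `weighted_median`, `egger` and leave-one-out require
  J ≥ 3; Egger raises a collinearity error when γ̂ has no variation.
- Harmonization resolves every anomaly to a logged drop (absent from the
  outcome table, palindromic, irreconcilable alleles) rather than an error;
  palindromic variants are never rescued by allele frequency.
- The pipeline fails fast on bad configuration but soft per
  exposure-outcome pair, reporting the pair with its reason.

## Limitations

The pipeline analyzes biallelic SNPs only (indel and multi-allelic records
are dropped at read time), takes LD as supplied data rather than computing
it from genotypes, substitutes an offline annotation table for interactive
phenotype-scan confounder lookups, and implements the single-pass PRESSO
outlier test rather than exhaustive multi-outlier search variants. Mode-based
estimators, multivariable MR and Steiger directionality filtering are out of
scope. Tier counts reproduced from the bundled published tables validate the
classification rules, not the upstream GWAS analyses that produced those
tables.
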