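# gutmr

Two-sample Mendelian randomization (MR) for gut-microbiota exposures and
chronic-respiratory-disease outcomes, built for epidemiologists who work from
GWAS summary statistics rather than individual-level data.

MR uses genetic variants as instrumental variables: because alleles are
randomly assorted at conception, a variant that raises the abundance of a
microbial taxon acts like a tiny randomized intervention on that taxon, so an
association between the variant and a disease outcome — mediated only through
the taxon — supports a causal effect. `gutmr` implements the full
summary-statistics workflow:

- **Instrument QC** — suggestive-significance selection (p < 1e-5), greedy LD
  clumping (10,000 kb window, r² ≥ 0.001), instrument-strength filtering
  (F = β²/se² ≥ 10), removal of outcome-associated (p < 1e-5) and
  confounder-annotated variants, and allele harmonization with unconditional
  removal of palindromic (A/T, C/G) variants.
- **Estimators** — per instrument j with SNP-exposure effect γ̂ⱼ (se γⱼ) and
  SNP-outcome log-odds Γ̂ⱼ (se Γⱼ), the Wald ratio β̂ⱼ = Γ̂ⱼ/γ̂ⱼ is pooled by:
  - *IVW*: β̂ = Σwⱼβ̂ⱼ / Σwⱼ with wⱼ = γ̂ⱼ²/se²_Γⱼ (weighted regression of Γ̂
    on γ̂ through the origin), multiplicative random effects
    φ = max(1, Q/(J−1));
  - *weighted median*: the 50% crossing of the inverse-variance-weighted
    cumulative distribution of ordered ratios, SE by parametric bootstrap;
  - *MR-Egger*: weighted regression Γ̂ⱼ = α + βγ̂ⱼ, the intercept α̂ estimating
    the average directional pleiotropy, t(J−2) inference;
  - *MR-PRESSO*: resampling-based global pleiotropy test, per-SNP outlier
    test (Bonferroni-adjusted empirical p), outlier-corrected IVW, and
    distortion test.
- **Sensitivity analysis** — Cochran's Q (IVW) and Rucker's Q′ (Egger)
  heterogeneity tests, the Egger-intercept pleiotropy test, and leave-one-out
  IVW refits flagging any single SNP that drives sign or significance.
- **Evidence tiers** — per-taxonomic-level Bonferroni thresholds
  (0.05/n with n = 9, 16, 20, 32, 119 taxa at phylum, class, order, family,
  genus): *highly probable* (IVW p survives Bonferroni), *probable*
  (IVW, weighted median and MR-PRESSO all nominally significant), *possible*
  (at least one nominally significant), struck to *none* on any pleiotropy,
  heterogeneity or leave-one-out failure.
- **Synthetic data** — a generator for two-sample summary statistics (and
  whole 211-taxon panels) with known causal effect, pleiotropy regime, LD
  structure and palindromic variants, so every stage is testable offline.

## Worked example

```python
import numpy as np
from gutmr import (SimConfig, simulate_pair, harmonize, ivw,
                   weighted_median, egger, presso, cochran_q)

cfg = SimConfig(seed=42, J=20, theta=np.log(1.25),
                prop_invalid=0.2, pleio_mean=0.02, pleio_sd=0.01)
exposure, outcome, ld, truth = simulate_pair(cfg)
inst = harmonize(exposure, outcome)

est = ivw(inst)
wm = weighted_median(inst, n_boot=1000, seed=7)
slope, intercept = egger(inst)
pres = presso(inst, n_sim=1000, seed=7)
q = cochran_q(inst)
```

which prints, when formatted:

```
J = 20 harmonized instruments (true theta = 0.2231)
IVW:             OR = 1.355 (1.275-1.441), p = 3.06e-22
Weighted median: OR = 1.430 (1.308-1.562), p = 3.27e-15
MR-Egger slope:  OR = 1.439 (1.305-1.587), p = 0.000
Egger intercept: -0.0049, p = 0.149
Cochran Q = 32.49 (df 19), p = 0.028
PRESSO global p = 0.082, outliers = []
```

The simulated taxon truly raises disease odds by 25% per unit exposure
(θ = ln 1.25 ≈ 0.223); all three ratio estimators recover an OR near 1.35–1.44
with confidence intervals excluding 1. The Egger intercept is compatible with
no *directional* pleiotropy (the planted direct effects are small relative to
their spread), while Cochran's Q (p = 0.028) correctly notices the extra
ratio heterogeneity those invalid instruments introduce — in the full
pipeline that heterogeneity flag would strike the taxon from the final
evidence tiers.

## Command line

```sh
gutmr simulate --seed 3 --out study/ --level genus=5 --snps 12 --theta 0.18
gutmr run --config config.yaml       # instrument QC -> estimators -> tiers
gutmr tier --pvals pvals.tsv --out tiers.tsv
gutmr replicate-tables               # counts from the bundled published tables
```

`gutmr run` reads a YAML configuration (exposure manifest, outcome tables,
LD map, confounder annotations, thresholds, master seed) and writes
`estimates.tsv`, `tiers.tsv`, `loo.tsv`, `summary.tsv`, `presso.json` and a
per-pair provenance log of SNP counts removed at each filter stage. Identical
configuration and seed reproduce every output byte-for-byte.

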