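# Methods

This note describes the statistical models implemented in `xpqtl`, the
default parameters and the reasoning behind them, what the synthetic
generator does and does not capture, and the package's known limitations.

## 1. Synthetic cohort generator

**Genotypes.** Haplotypes are latent AR(1) Gaussian processes per
chromosome, thresholded at the quantile of each variant's effect-allele
frequency; two independent haplotypes sum to a hard-call dosage in
{0, 1, 2}. Thresholding a Gaussian attenuates correlation, so the latent
autocorrelation is calibrated numerically (bivariate-normal orthant
probabilities solved by root-finding) such that the *allele-level* adjacent
correlation equals the requested `ld_rho`. With i.i.d. haplotypes the
dosage correlation equals the allele correlation, which is what the tests
verify.

**Protein and measurements.** A true log-scale abundance is
`sum(beta_true * dosage) + biological noise`; each platform observes the
shared abundance plus platform-specific noise (`corr_bio` controls how
much of the non-genetic variance is shared). Epitope artifacts
(`epitope_shift_A/B`) act on the *measurement* of one platform only, never
on the true abundance — this is the mechanism that produces
platform-specific cis pQTLs. Phenotypes are wired in one of two modes:
`abundance` (phenotype depends on the true protein level) or `proteoform`
(phenotype depends directly on a protein-altering allele, so it is
conditionally independent of abundance given genotype).

**Technical layer (platform A only).** Measured values are exponentiated
to an intensity scale, multiplied by per-sample, per-dilution-bin
log-normal scale factors (`scale_sd = 0.1`), floored at a detection limit,
and accompanied by buffer blanks generated near the floor. Platform B is
delivered as log-scale scores without a technical layer, mirroring the
asymmetry between raw aptamer fluorescence and antibody NPX-style data.

**Scenarios.** Five named configurations on an 18-variant cis region:
`shared-pqtl` (one cis abundance variant, effect 0.7), `epitope-a-only`,
`epitope-b-only` (artifact −0.8 on one platform, no true effect),
`distinct-signals` (two unlinked variants, one artifact per platform, low
regional LD), and `proteoform-phenotype`. Default cohort sizes are
n = 2000 with a nested subsample of 485. These are the package's study
conditions: 485 is kept exactly because the interaction-test operating
characteristics are specified at that size, and 2000 is large enough for
genome-wide-significant cis signals at effect 0.7 while keeping hundreds
of replicate cohorts affordable on one CPU.

## 2. Assay QC

* **Adaptive median normalisation.** Per sample and per dilution bin, the
  scale factor is the median over bin analytes of (reference / measured);
  the cohort medians serve as reference when none is supplied. Samples with
  any factor outside 0.25–4 are excluded. Recovering simulated scale
  factors with r > 0.99 requires many low-variance analytes, which is why
  cohorts carry 40 background analytes spread round-robin across the three
  dilution bins.
* **Limits of detection.** Per analyte over ≥ 3 blanks: median + 4.9 ×
  (unscaled) median absolute deviation.
* **Outliers.** Values outside median ± 5 × MAD per analyte; a MAD of zero
  flags nothing (a degenerate column is not evidence of outliers).
* **Inverse-normal transform.** z = Φ⁻¹((rank − 0.5)/n) with average ranks
  for ties; constant input is rejected.
* **Residualisation.** OLS on covariates with an intercept; exactly
  collinear covariate columns are reported by name.

## 3. pQTL mapping

* **GWAS.** Per-variant OLS of the prepared score on dosage, t-distribution
  p-values, pairwise deletion of missing dosages. Monomorphic variants are
  returned with `usable = False` rather than dropped, so variant sets stay
  aligned across traits.
* **Meta-analysis.** Fixed-effects inverse-variance weighting after allele
  harmonisation (swapped allele pairs flip the sign and frequency);
  irreconcilable allele pairs are dropped and logged in `attrs["dropped"]`.
* **Thresholds.** 5×10⁻⁸ divided by the number of reagents: 4979 aptamer
  reagents give 1.004×10⁻¹¹ and 1104 antibody measures give 4.5×10⁻¹¹.
* **Regions.** Significant variants ± 500 kb merged when overlapping or
  adjoining; the extended MHC (chr6:25.5–34.0 Mb) is always one region.
  Leads are the smallest p, ties broken by position; output is
  deterministic and input-order invariant.
* **Cis/trans.** Cis iff the lead is on the target gene's chromosome within
  500 kb of the gene body; targets without a mapped gene body are trans.
* **Conditional signals.** Forward stepwise selection (entry p < 5×10⁻⁸ in
  the joint model), skipping candidates with r² > 0.1 to any selected
  variant, with final-model pruning of variants that lose significance.

## 4. Cross-platform consistency

The decision tree evaluates each region–target pair in order:

1. **Power filter.** The larger platform's primary lead is rescaled to the
   smaller sample via se_target = se·√(n_source/n_target); predicted
   p ≥ 10⁻⁵ → `underpowered`. This is deliberately checked first: calling a
   pair platform-specific when the smaller sample could never have seen the
   effect would be a false discrepancy.
2. **LD/sign test.** When both platforms have signals, the best-LD pair
   over all lead and conditional variants is tested at r² > 0.6 with signs
   harmonised to a common effect allele: concordant → `shared`, discordant
   or unlinked → `distinct_signals`.
3. **Cross-platform look-up.** One-sided discoveries check the discovering
   lead in the other platform's summary statistics; p < 10⁻⁵ with a
   concordant sign rescues the pair to `shared`, otherwise `specific_A` /
   `specific_B`.

The genotype-stratified analysis fits OLS of the antibody measure on the
aptamer measure, dosage and their product; the interaction t-test reads as
a test of genotype-dependent between-platform scaling, with per-genotype
Spearman correlations for strata of ≥ 10 individuals. Discovery across
many pairs uses Benjamini–Hochberg at FDR 20% — permissive by design, as
interaction tests at n = 485 have limited power.

## 5. Colocalisation and network

Per-variant Wakefield log approximate Bayes factors,
lABF = ½[ln(se²/(se²+W²)) + z²·W²/(se²+W²)], with effect-size prior sd
W = 0.15 for quantitative traits (0.2 for binary). Five-hypothesis
posteriors use per-variant priors p1 = p2 = 10⁻⁴ and a conservative shared
prior p12 = 10⁻⁶; all sums run in log space via log-sum-exp, and the
distinct-variants cross term S1·S2 − S12 is computed as
l1 + l2 + log1p(−exp(l12 − l1 − l2)), clamped to −∞ when numerically
non-positive (single-variant regions). This keeps posteriors exact to
~10⁻¹⁵ against brute-force enumeration while surviving lABFs in the
hundreds.

The screen pairs protein regions with suggestive evidence (p < 10⁻⁶)
against suggestive phenotypes, retains PP4 > 0.8 with lead-variant
r² > 0.8 — the LD filter is what rejects proteoform scenarios, where
posterior support and lead identity disagree — and reruns on
lead-conditioned protein statistics where a secondary signal (conditional
p < 5×10⁻⁸) exists. Edges carry the phenotype direction aligned to the
protein-increasing allele; both-platform edges are `consistent` or
`opposing`, otherwise platform-specific.

## 6. Determinants of measurement specificity

* **Shadow-feature selection.** Each of 20 rounds appends independently
  permuted shadow copies of every feature, fits a 500-tree random forest
  (max_features = ⅓ for regression, √p for classification — the classic
  defaults) and scores a hit when a feature's importance exceeds the
  maximum shadow importance. Hits follow Binomial(20, ½) under the null;
  two-sided binomial tests with Bonferroni adjustment at α = 0.01 yield
  confirmed/rejected/tentative. The default importance measure is mean
  decrease in impurity — the convention of the reference Python
  implementation — because sklearn's permutation importance was ~8× slower
  with identical decisions on planted-feature checks; permutation
  importance remains available via `importance="permutation"`. Bootstrap
  importance distributions (500 resamples) are reported for confirmed
  features.
* **Platform-specificity factors.** One univariate logistic fit per factor
  with HC1 sandwich covariance; skew-reducing transforms (log for apparent
  binding constants, √ for counts and variance fractions) are applied
  first. Separation is flagged, not fatal. Note that HC1 intervals
  under-cover slightly in small samples (measured ~93.5% at n = 300 for a
  nominal 95% interval).
* **Variance decomposition.** Joint OLS of the between-platform difference
  on all explanatory variables; variable j's share is Var(x_j·β_j)/Var(y)
  and the residual share is 1 − R². For orthogonal predictors this equals a
  random-effects variance partition; with correlated predictors the shares
  need not sum to one and a warning is raised.

## 7. Numerical and engineering choices

* All stochastic routines take explicit integer seeds and use
  `numpy.random.default_rng`; cohort generation is bitwise reproducible.
* Standard statistics are delegated (BH via statsmodels, forests via
  scikit-learn, log-sum-exp via scipy, GraphML via networkx); the authored
  components are the consistency decision tree, the coloc engine, the
  conditional stepwise selection and the shadow-feature procedure.
* On-disk formats are plain text: TSV matrices with sidecar metadata,
  minimal GT-only VCF (read back through pysam), BED (0-based half-open on
  disk, converted to the in-memory 1-based inclusive regions), summary
  statistics with a fixed column contract.

## 8. Limitations

* The generator is a *mechanism* model, not a cohort emulator: one cis
  region, hard-call genotypes, Gaussian noise, no relatedness, population
  structure, batch structure beyond per-sample scale factors, or
  genotyping/imputation error. Headline cohort-scale results (e.g. median
  between-platform correlations, genome-wide region counts) are out of
  scope by construction.
* Colocalisation assumes at most one causal variant per trait per region;
  the conditional rerun mitigates but does not remove this.
* The fixed-effects variance decomposition and the HC1 logistic intervals
  are simplifications of mixed-model partitioning and exact small-sample
  inference respectively; both are documented above with their measured
  behaviour.
* Predicted p-values assume the effect size is identical in the subsample
  and that se scales exactly with 1/√n, i.e. equal residual variance and
  allele frequency across samples — guaranteed here by nested sampling,
  only approximate in real split cohorts.
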