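# Methods

This note documents the statistical models, the defaults, and the numerical
choices behind `snp_epistat`, in the spirit of a methods appendix: what is
assumed, what is estimated, and what the synthetic-data checks do and do not
demonstrate.

## Study design and data model

The unit of analysis is one subject with: case/control status; a biallelic
SNP genotype coded as the dosage of the minor A allele (0/1/2, fixed by the
schema rather than re-estimated per file, so effect directions cannot flip);
an HLA carrier flag (≥1 copy of a tagging allele for the risk haplotype,
optionally derived from a CC/CT/TT tag genotype); sex; age; and, for cases
only, disease course (RR/SP), age of onset (AOO, years), disease duration,
EDSS, and MSSS. MSSS is consumed as a precomputed column — the reference
lookup that maps (EDSS, duration) to MSSS is out of scope. Missing cells are
retained and removed per analysis (complete-case); no imputation is offered
because none is assumed in the target design.

## Hardy-Weinberg testing

Pearson χ² with 1 degree of freedom (three genotype classes, one estimated
allele frequency), no Yates correction, with expected counts
`(n(1−q)², 2nq(1−q), nq²)` and q estimated from the tested group itself.
Monomorphic input is an error rather than χ²=0: HWE is undefined without
both alleles. An exact test is deliberately not the default — the Pearson
form is what this class of studies reports.

## Odds ratios

* **Crude:** cross-product with the Woolf log-scale interval. The normal
  quantile is pinned at `1.959964` so printed intervals are reproducible to
  the last digit. The Haldane–Anscombe +0.5 correction is applied to all
  four cells only when at least one cell is zero, never otherwise; tables
  with an empty margin have no defined OR and raise.
* **Adjusted:** Newton maximum-likelihood logistic regression
  (statsmodels), tolerance 1e-10, at most 100 iterations. Non-convergence
  raises; any |coefficient| > 15 is treated as complete or quasi-complete
  separation and raises a dedicated error instead of reporting a meaningless
  huge OR. Per-contrast Wald p-values are the primary output because the
  target table layout reports one p per OR row; a per-model likelihood-ratio
  p is emitted alongside, since reference web tools for these scans test the
  genotype term(s) by LRT. For a saturated single-predictor model the Wald
  interval coincides with the Woolf interval (tested to 4+ significant
  digits).
* **Allele contrast** is computed crude at chromosome level (each subject
  contributes two alleles). Covariate adjustment is not offered for this
  model: covariates attach to subjects, not chromosomes, so an "adjusted
  allelic OR" is not a well-defined estimand here.
* Inestimable contrasts (an empty exposed or reference stratum) are returned
  flagged rather than dropped, so scan output always has the full model list.

## Synergy factor

Two binary carrier traits partition subjects into 4 joint-exposure groups;
with the double-negative group as reference, `SF = OR11/(OR10·OR01)`.

* **Crude 8-cell route:** `ln SF` is a linear combination of 8 log-counts;
  its Wald standard error is `√(Σ 1/cell)` over all eight cells, the z test
  is two-sided normal. Empty cells get the +0.5 correction on all 8 cells
  (flagged); two empty cells within one case/control margin make SF
  undefined.
* **Logistic route:** `status ~ f1 + f2 + f1:f2 (+ covariates)`;
  `SF = exp(β_interaction)`. With no covariates the model is saturated on
  the 8 cells and reproduces the crude SF exactly — this identity is
  property-tested and is the package's internal cross-check between the two
  routes. Covariate-adjusted SF (age, sex) is only available from
  subject-level data.
* The SNP factor uses dominant ("carrier") coding; the second factor is the
  HLA carrier flag, but any predicate works — e.g. sex, which provides the
  SNP×sex interaction check.
* Inference is Wald on the log scale throughout; no bootstrap, matching the
  normal-theory reporting of the target design.

## Analytic power

For a one-stage case-control design with prevalence K, risk-allele frequency
p, and genotype relative risk γ: population genotype frequencies are HWE(p);
penetrances are `f0·(1, γ, 2γ−1)` under the **additive** model (risk added
per allele on the penetrance scale), `f0·(1, γ, γ²)` under multiplicative,
with f0 solved from K. Cases are penetrance-weighted, controls are sampled
as unaffected (`(1−f)`-weighted) — at sub-1% prevalence this is practically
identical to population controls but the choice is explicit and testable.
The test whose power is computed is the two-sided allele-frequency z test
with the variance evaluated at the alternative
(`p₁(1−p₁)/2N₁ + p₂(1−p₂)/2N₂`); power is the tail of the non-central χ²(1)
at non-centrality z². At γ=1 power equals α exactly.

The additive-penetrance parameterization with this test variant is the
default because it is the combination that reproduces the published power
figures for this design class (88.5% and 22.3% at γ = 1.3 and 1.1 for
579/1145 subjects, prevalence 0.1%, p = 0.31, α = 0.05); the multiplicative
per-allele variant gives materially higher values (93%/24%) and is kept as
an explicit alternative. The allele-relabeling symmetry γ → γ/(2γ−1),
p → 1−p (additive) and γ → 1/γ (multiplicative) holds exactly and is tested.

## Phenotype regression

Case-only OLS of AOO or MSSS on one encoded genotype term plus covariates.
Covariate sets follow the target design: AOO whole-cohort adjusts for sex
and HLA carriage, within-stratum for sex only (the stratifier is constant
within a stratum); MSSS additionally adjusts for AOO. The codominant coding
reports the joint F test of its two indicators. "Best model" — the coding
with the smallest genotype-term p, ties broken by AIC — is a reporting
convention only and is flagged as such; it is not a model-selection
inference. Zero-residual-variance phenotypes return a degenerate result
(slope 0, p 1) instead of failing; rank-deficient designs raise and name the
collinear columns.

## Synthetic cohort generator

The generator draws a virtual population and samples retrospectively, so the
covariate-adjusted estimators are exercised under the actual case-control
sampling scheme rather than on conveniently prospective data.

* Genotype ~ HWE(MAF 0.31); HLA tag copies ~ HWE at the allele frequency
  implied by a 20% population carrier rate; the two loci are drawn
  independently (no linkage simulation).
* Disease: `logit P(D) = β₀ + β_g·g + β_h·h + β_int·(g≥1)·h` with defaults
  β_g = ln 1.07 (per allele), β_h = ln 3.77, β_int = ln 0.62 — the
  effect-size scale of the design this package models. β₀ defaults to 1%
  baseline odds: case-control studies oversample cases, and a realistic
  population can then supply the default 579/1145 target within the
  100×-target population cap (the cap and target-feasibility check raise a
  clear error otherwise). The closed-form prevalence, joint-exposure cell
  probabilities, crude carrier-level component ORs, crude SF, and crude
  dominant OR implied by any configuration are computed exactly and returned
  as the truth record.
* Covariates: age and sex are generated with group offsets (controls older:
  52 ± 21 vs cases; cases more often female) but do not enter the disease
  model — they exist to exercise confounder adjustment machinery, not to
  confound the genotype (which they cannot, being independent of it).
  Case age is onset + duration (duration ~ N(11.9, 7.1) clipped to
  [0.5, 60]), which keeps the onset distribution untruncated and makes the
  AOO/duration/age invariant exact.
* Phenotypes (cases only): AOO ~ N(29.7, 9.8) plus an optional genotype
  shift under a chosen coding; EDSS ~ N(3.56, 1.56) rounded to half points
  in [0, 10]; MSSS ~ N(4.41, 2.09) clipped to (0, 10); SP course probability
  `expit(−1.65 + ln(0.41)·(g≥1))`, i.e. ~12% SP overall with minor-allele
  carriers under-represented among SP.
* Determinism: one integer seed, one generator, fixed draw order
  (genotype → HLA copies → covariate latents → status → phenotypes). The
  covariate latents are drawn as uniforms before status and transformed to
  their group-specific distributions afterwards, so the draw order is stable
  even though the offsets depend on status.

**What passing synthetic checks shows — and does not.** Recovery and
coverage results demonstrate that the estimators are consistent and their
intervals calibrated *under the generating model*: independent loci, exactly
logistic disease risk, covariates independent of genotype, no genotyping
error, no missingness. Real cohorts violate several of these (LD between the
SNP and the HLA tag, secular covariate structure, measurement error in EDSS
and onset dating), so the checks validate the software and the statistics,
not the biology.

## Problem sizes used in the checks

Calibration checks run at the scale of the design itself: 500 replicate
cohorts of 579/1145 for CI coverage of the synergy factor and the adjusted
per-allele OR (both observed ≈ 0.94), 1000 replicates of a 700/1300 null
cohort for the SF z-test type-I error, 5000 simulated studies for the
empirical power oracle, and 3×10⁶ subjects for the Monte-Carlo check of the
penetrance-conditioned genotype frequencies. These sizes give Monte-Carlo
error comfortably below each test's tolerance.

## Known limitations

* Single SNP, single binary co-factor: no haplotypes, no LD modelling, no
  genome-scale input formats.
* No multiple-testing correction anywhere, by design fidelity to the
  analysis style being modelled.
* The adjusted-OR p-values depend on individual covariates, so published
  adjusted values can only be matched in distribution (direction and
  magnitude on synthetic cohorts), never digit-for-digit from counts.
* The power module covers one-stage designs only, and not power for
  interaction (SF) tests.
* Interaction inference is normal-theory; for very sparse joint-exposure
  tables the Wald interval on ln SF is approximate and the +0.5-corrected
  estimate is biased toward the null.
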