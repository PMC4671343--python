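# Methods

## Summary-level model

All estimators operate on per-SNP summary statistics: for SNP *i* and a
trait, a per-allele effect β_i, its standard error s_i, the effect
allele, and optionally the effect-allele frequency (EAF) and p-value.
The exposure is ln-transformed, SD-standardized plasma homocysteine, so
exposure betas are in SD units per allele; binary outcomes are on the
lnOR scale, continuous outcomes on their measurement scale.

### Harmonization

Every analysis uses the exposure-increasing allele as the effect
allele. `harmonize` intersects the exposure and outcome rsid sets
(exposure order preserved, exact string match, no LD proxies), flips
any exposure record with a negative beta (β → −β, EAF → 1−EAF), and
flips each outcome record whose stated effect allele disagrees with the
harmonized exposure allele. The source tables record only the effect
allele, so a flipped exposure record's new allele is marked `other`;
alignment decisions are made from allele identity under a
forward-strand assumption. An outcome allele equal to the strand
complement of the exposure allele is ambiguous (strand flip vs allele
swap); it is treated as the other allele with a logged warning — the
packaged panel contains no palindromic pair with EAF near 0.5, so no
frequency-based inference is implemented. Because `other` stands in
for an unnamed allele, harmonization is involutive and idempotent in
all *numeric* content (beta, SE, EAF) but cannot restore the letter of
an allele it was never given. All flips and drops are recorded in the
report's provenance block.

### Score combination

The per-allele effect of the unweighted allele-count score on a trait
is the inverse-variance weighted mean β = Σβ_i s_i⁻² / Σ s_i⁻² with
SE = (Σ s_i⁻²)^(−1/2). This is exact for the fixed-weight projection
of independent per-SNP estimates and coincides, up to sampling noise,
with regressing the trait directly on the allele-count sum (a SNP's
summary SE is inversely proportional to the SD of its allele count, so
the inverse-variance weights reproduce the regression's implicit
variance weights); the test suite checks this equivalence on synthetic
cohorts. SNPs are assumed mutually independent — the two same-locus
pairs in the panel are treated (and simulated) as independent signals,
a documented caveat. No effect-size-weighted score, Cochran's Q,
MR-Egger or median estimator is provided: the design under study uses
the unweighted score and the Wald ratio only.

Instrument strength is reported as F = z² = (β/SE)². From the packaged
two-decimal inputs F ≈ 387; the published F = 650 (and the narrative
score effect 0.092 vs the reproducible 0.088) derive from unrounded
source data, so those two quantities are asserted as formula properties
and flagged `rounding-limited` rather than matched numerically.

P-values are two-sided standard normal; the log-survival function is
used past the underflow point, so p is reported as 0 only below
~1e-300. 95% CIs use 1.96 verbatim, matching the reporting precision
of the source analysis.

### Wald ratio and delta-method SE

β_IV = β_out/β_exp, with delta-method SE
|β_IV|·sqrt((s_exp/β_exp)² + (s_out/β_out)²). That textbook form is
singular at β_out = 0 although its limit is not, so the implementation
uses the identical expression
sqrt(β_out²·s_exp²/β_exp⁴ + s_out²/β_exp²), finite whenever
β_exp ≠ 0 and equal to s_out/|β_exp| at β_out = 0. β_exp = 0 raises a
weak-instrument error; a score-exposure |z| < 3 yields a prominent
report warning but not a failure. No Fieller or other weak-instrument
interval is implemented — the instrument here has z ≈ 23, where the
first-order approximation is accurate (validated against the
Monte-Carlo SD of the simulated ratio, and against individual-level
two-stage least squares on synthetic cohorts).

## Synthetic cohort

The generator emulates the observational cohort the design's
individual-level arm was run on: n = 1,016 subjects aged ≈ 70 (ages
jittered around 70.2, sexes balanced), five biallelic SNPs drawn
Binomial(2, EAF) — Hardy–Weinberg, no LD — at the published
frequencies (0.20, 0.34, 0.79, 0.55, 0.47), and 12% baseline diabetes
prevalence. The structural equations, parameters and draw order are in
the `cohort` module docstring. Key choices:

- **Exposure variance budget.** Per-SNP effects default to the
  published values (0.10, 0.16, 0.05, 0.07, 0.06 SD per allele), giving
  a genetic variance of ≈ 0.0197 — the score explains ≈ 2% of
  ln-exposure variance, which with n = 5,000 yields a score-exposure
  z ≈ 10 and with the source GWAS sample sizes the published z ≈ 25.
  The residual SD is set so the *theoretical* raw-exposure variance is
  1; the exposure is then standardized within-sample (empirical mean
  and SD), matching the ln-then-SD transformation of the original
  design. The source analysis does not report the variance explained in
  its own cohort; this default follows from the published betas and
  EAFs and is not calibrated further.
- **Confounding and reverse causation.** A standard-normal confounder
  C enters the exposure with weight γ_x and every outcome with γ_y.
  The reverse-causation path feeds the *glucose* liability
  (γ_y·C + its unit-variance residual) back into the exposure with
  weight `reverse_effect`; it is not modelled for the binary trait. A
  configuration whose genetic + confounder + reverse variance reaches 1
  is rejected with a variance-budget error.
- **Binary outcome.** T2D is Bernoulli with
  logit p = logit(prev) + θ·X + γ_y·C; the intercept hits the baseline
  prevalence exactly at covariate means, so the marginal prevalence
  deviates slightly (by Jensen's inequality) when θ or γ_y is large.
  Summary effects for binary traits are lnOR from per-SNP logistic
  fits (the consortium convention); no liability-scale conversion.
- **GWAS reduction.** Continuous traits: per-SNP OLS of trait on
  allele count, optionally age/sex-adjusted. Binary: per-SNP logistic
  regression (≥ 10 cases required). Monomorphic SNPs are excluded with
  a warning. EAFs are taken from the sample.
- **Determinism.** One `numpy.random.default_rng(seed)` per cohort;
  sub-streams are drawn in a fixed, documented order so changing one
  component does not reshuffle upstream draws. Identical config + seed
  is bit-identical.
- **Serialization.** Cohorts round-trip as TSV (genotype columns first,
  then exposure/confounder/age/sex, then outcomes). Gene and allele
  labels are not stored in the TSV; summaries regenerated from a
  reloaded cohort carry `other` as the allele label, which harmonizes
  consistently because exposure and outcome summaries then share it.

What passing simulation tests show — and what they do not: the
generator has no LD, no population stratification, no genotyping error
or missingness, no assay noise, no survival outcomes, and its
confounder is a single Gaussian. Recovery and coverage results
therefore validate the *estimator and pipeline logic* under the stated
model, not robustness of the design to violations (pleiotropy, weak
instruments, stratification) that real data may present.

## Validation protocol sizes

The acceptance-style checks run 500 replicates per causal-effect value
(θ ∈ {0, 0.1, 0.3}) at n = 5,000 for bias (|bias| < 3 Monte-Carlo SEs)
and 95% CI coverage (accepted in [0.92, 0.975]); 150 replicates for the
confounded-null contrast; 20 replicates compared against two-stage
least squares (agreement within 2 combined SEs); and 2×10⁵ − 3×10⁵
Monte-Carlo draws for the delta-method SE check (within 10% at
instrument z ≈ 23). These sizes give Monte-Carlo error comfortably
inside the stated bands while keeping the whole suite under a minute
of simulation time.

## The published-analysis rerun

`reproduce-paper` compares three kinds of quantity: (i) score-level
effects recomputed from the packaged two-decimal per-SNP tables;
(ii) causal estimates recomputed from the *published* score-level
coefficients (these reproduce the published causal OR 1.09 and the
glucose effect 0.002 exactly to printed precision); and (iii) the
end-to-end causal estimates from (i), where compounding of input
rounding is largest (T2D causal OR 1.12 vs the published 1.09 — the
printed score-T2D row 0.008 is itself a casualty of rounding, as the
two-decimal per-SNP inputs recombine to 0.010). Each cell carries a
`match` or `rounding-limited` flag computed at the published precision.
Notably the end-to-end insulin causal estimate (−0.019) agrees with the
published value even though the published ratio of *printed*
score-level inputs (−0.002/0.092 = −0.022) does not — the recombined
score beta −0.0017 is closer to the unrounded source than the printed
−0.002.
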