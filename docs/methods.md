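# Methods

This note documents the models implemented in `cvdstrat`, the
assumptions behind the synthetic-cohort generator, the numerical
choices that matter, and the limits of what the test suite
demonstrates.

## The analysis model

The pipeline estimates the joint predictive value of a combined
genetic score and a clinical risk equation for incident cardiovascular
disease in a longitudinal cohort.

**Additive scoring.** A trait score is PRS_i = Σ_v d_iv β_v over the
weight panel's variants, where d_iv counts the panel's effect allele
(flipped to 2 − d when the genotype file codes the other allele;
variants matching neither allele, or absent, are skipped and counted).
Missing dosages are mean-imputed per variant. Scores are normalized by
the rank-based inverse-normal transform with the Blom offset,
Φ⁻¹((r − 3/8)/(n + 1/4)). We read "normalized to a normal
distribution" as a normalizing transform rather than mere
standardization; z-scoring is available as a configuration
alternative, and every downstream step is invariant to that choice up
to the monotone map.

**LOGO cross-fitting.** Where no external weight panel exists, weights
are estimated in-cohort without leakage: samples are partitioned
uniformly at random into k groups (default 10, unstratified); for each
held-out group a per-variant univariate logistic GWAS runs in each of
the other k − 1 groups; the group-level estimates are pooled by
fixed-effect inverse-variance meta-analysis
(β = Σ β_j/se_j² / Σ 1/se_j², se = (Σ 1/se_j²)^(−1/2)); meta betas with
p below a threshold (default 1.0, i.e. all variants) become the
weights for the held-out group only. With linkage-free variants the
marginal betas are unbiased for the causal effects, which is why no
shrinkage step is needed here; the weighting hook accepts externally
shrunk panels when linkage matters. With k = 2 there is a single
training group and the pooling step is skipped.

The GWAS itself is a two-parameter (intercept + dosage) Newton–Raphson
solver vectorized across variants, cross-checked against statsmodels
at 1e-6. Fits drifting into separation are clamped at |β| = 10,
flagged, and given the Rao score-test p-value, which exists at the
null regardless of separation.

**Combination weights.** One multiple logistic regression of prevalent
disease on all trait scores plus age and sex; the trait coefficients
(log-odds per SD, since scores are normalized) are the combination
weights. The intercept and covariate coefficients are excluded from
the weighted sum — covariates re-enter through Cox adjustment and
through the clinical equation itself. Genetic groups are the 20%/80%
empirical quantiles (linear interpolation) of wPRSsum over a
configurable base set; the default base set is the full genotyped
cohort *before* exclusions, because published stratum sizes are not
exact quintiles of the post-exclusion analysis set, which is what one
obtains when cutpoints predate the exclusions. Interval convention:
[min, q20), [q20, q80), [q80, max] — a score exactly at q20 is
intermediate.

**Subset association scan.** For each nonempty trait subset the
combination fit is repeated and the subset's weighted sum tested
against prevalent disease. The reported odds ratio is per SD of the
fitted sum (age/sex-adjusted), making rows comparable across subset
sizes. The reported p-value is *not* the Wald test of that sum: the
sum's weights are estimated on the same response, so the Wald test is
anti-conservative (empirically ~15% type-I at the 5% level in null
simulations). Instead each row carries the k-df likelihood-ratio test
of the subset's trait coefficients against the age/sex-only model,
which is calibrated under the null.

**Clinical equations.** The sex-specific linear sums use the
Korean-recalibrated pooled-cohort coefficient sets shipped with the
package. Encoding: exactly one blood-pressure pathway is active per
person — TRSBP = SBP and UNSBP = 1 for treated individuals, mirrored
otherwise — the only reading that keeps the treated/untreated terms
mutually exclusive under the pooled-cohort template. Conversion to
10-year risk uses risk = 1 − S₀(10)^exp(sum − mean_sum). The anchors
(per-sex mean sum and 10-year baseline survival) are intentionally not
hard-coded: the published source does not print them, so they are
estimated on the target cohort — mean of the sums and Kaplan–Meier
survival at 10 years per sex, computed on the incident-analysis
(disease-free) set — or supplied in configuration. Using the marginal
KM as S₀ is a first-order approximation to the at-mean-covariates
baseline survival; its error grows with the spread of exp(sum −
mean_sum), which is why the calibration-closure test operates in a
small-risk regime (~1% 10-year risk), where the approximation is
within one percentage point. The 7.5% threshold splits low/high
clinical risk, boundary inclusive on high.

**Survival evaluation.** Cox proportional-hazards fits use the partial
likelihood with Efron's tie correction — the biannual grid makes event
times heavily tied, where Breslow is visibly biased — with Wald SEs
and p-values per covariate. Stratum analyses fit indicator covariates
for the non-baseline groups plus age and sex, and report the indicator
hazard ratios. Harrell's C follows the censored-aware pair convention
(pairs are comparable when the earlier time is an event, or at tied
times when exactly one member is censored; score ties count ½) and is
implemented directly rather than through a library so the convention
is explicit; it is tested against exhaustive pair enumeration. The
five predictive models are: (1) age + sex; (2) wPRSsum; (3) wPRSsum +
age + sex; (4) PCE; (5) wPRSsum + PCE — model 5 omits age and sex
because the clinical equation already encodes them. Each model's
C-index is that of its fitted Cox linear predictor within the
evaluation subgroup (the documented choice; for single-covariate
models this equals the raw-score C by rank invariance). The PCE enters
models 4–5 as the per-sex mean-centered linear sum: raw sums are on
incompatible scales across sexes (the coefficient sets are disjoint),
while the centered sum is the log-relative-hazard scale of the
recalibrated risk transform and is cross-sex comparable.

**Information ordering.** Combination weights use prevalent cases on
the full genotyped cohort; genetic cutpoints use the same
pre-exclusion base; prevalent samples and samples missing any clinical
covariate are then excluded, and all survival analyses run on the
remaining incident-analysis set. Exclusion counts are reported per
reason and must reconcile with the input size; silent drops are
treated as bugs.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not any particular genome.

* **Genotypes**: m independent biallelic variants, MAF uniform on a
  configurable range (default 0.05–0.5), dosages binomial(2, maf) —
  Hardy–Weinberg by construction, no linkage. Per-variant metadata
  (empirical frequency, call rate, HWE p, simulated imputation
  quality ~ U(0.9, 1)) feeds the QC stage; an optional corruption
  profile injects variants and samples violating each QC rule for
  exact-count filter tests.
* **Causal architecture**: per trait, a random subset of variants
  (default 20 of 200) receives N(0, 0.25²) effects; the per-sample
  trait score is the additive sum. The total genetic burden is the
  standardized sum of the four standardized trait scores.
* **Covariates**: per-sex truncated normals for age, SBP, TC, HDL and
  per-sex Bernoulli rates for smoking, blood-pressure treatment and
  diabetes, with defaults matching the published per-sex summary
  statistics (51.72% women; male/female smoking 48.76%/3.40%; etc.).
  Because the published moments describe the observed, range-restricted
  age column, the sampler inverts the truncation so the *truncated*
  mean matches exactly. A caveat: no truncated normal on [40, 69] can
  reach the published SD of 8.85 (the family's supremum is the uniform
  limit, ≈8.37), so the age SD is matched as closely as the family
  allows (≈8.2) while the mean is exact.
* **Prevalent disease**: probit liability threshold. Liability is the
  standardized genetic burden plus 0.5·z(age) plus a male offset
  (0.3), and P(prevalent) = Φ(a + 0.5·z(liability)) with the intercept
  solved so the expected prevalence equals the target (0.78%)
  exactly.
* **Incident events**: exponential proportional hazards,
  h_i = h₀·exp(β_g·G_i + β_c·C_i), with G the standardized genetic
  burden, C the within-sex standardized clinical (PCE) sum, defaults
  β_g = 0.18 and β_c = 0.55 per SD — magnitudes that reproduce the
  qualitative ordering of the published group contrasts (genetic HR
  per SD ≈ 1.15–1.2, clinical high-vs-low HR ≈ 2–3.5) without being
  fitted to them. Events are observed at the first biannual visit at
  or after occurrence (interval detection by survey); otherwise the
  sample is censored at its last attended visit. Planned follow-up
  ends at 16 or 18 years with equal probability (a two-wave enrolment
  window against a fixed final survey), and after each attended visit
  a sample drops out with probability 0.0514. The dropout rate and
  baseline hazard (0.00659/y) were solved jointly by large-n
  simulation so the expected mean follow-up is 13.31 years (median
  16) and the expected incident fraction 9.97% of the full cohort.
* **Determinism**: a single seed drives independent child generators
  for genotypes, covariates, effects, prevalence and survival;
  identical (parameters, seed) reproduce every emitted file
  byte-for-byte.

What the generator does **not** emulate — and hence what passing tests
cannot show about real data: linkage disequilibrium (so no shrinkage
weighting is exercised), population structure and relatedness,
genotyping batch effects, covariate measurement error, recall bias in
self-reported events, competing risks, and time-varying covariates.
Parameter-recovery results transfer to real cohorts only insofar as
the proportional-hazards and additive-liability assumptions hold
there.

## Numerical choices

* Cox fits run lifelines' Newton–Raphson with tightened stopping rules
  (`precision 1e-13`, relative-LL `1e-12`): the default
  newton-decrement rule discards its final computed step, leaving β̂
  about 1e-6 away from the optimum on small tied datasets — inside the
  default tolerance but outside ours, since the oracle tests compare
  at 1e-6.
* HWE is the 1-df chi-square goodness-of-fit test against expected
  counts from the empirical allele frequency (the standard choice at
  cohort-scale counts; an exact test is a noted extension). A
  monomorphic variant returns p = 1 — every genotype class is
  structurally determined, so there is no departure to measure.
* QC comparisons are strict on the removal side (call rate < 0.95
  removes; exactly 0.95 survives), mirroring the "<" phrasing of the
  thresholds. "Excessive heterozygosity" is ±3 SD of the cohort mean
  heterozygosity; the source gives no number. Filters run
  variants-then-samples, one pass, and are idempotent.
* Missing dosages are NaN (a sentinel outside [0, 2]); call rates
  derive from it.
* Quantiles are linear-interpolation (NumPy default, type 7); group
  intervals are half-open as documented above.
* Logistic fits that fail to produce finite standard errors (complete
  separation — possible with very few prevalent cases at small n)
  raise with advice to enlarge the cohort rather than returning
  degenerate estimates.

## Scaled-down test sizes

The test suite and acceptance checks run the full-size cohort
(n = 7,612) only for generator calibration; pipeline-level and
replicate-based checks use n ≈ 1,200–3,000 with 30–80 variants, and
50 replicates for the structural-monotonicity checks. These sizes are
the package's chosen trade-off between Monte-Carlo resolution and
suite runtime; at them, group-level hazard-ratio orderings and
C-index dominance are majority-stable across replicates while
individual contrasts are often non-significant, exactly as the
worked example shows.

## Known limitations

* The published hazard ratios, odds ratios and C-indices of the
  original cohort are not reproducible here: the cohort is not public,
  and the generator is calibrated to its demographic table only, not
  to its effect-size table.
* LOGO weighting inside the pipeline uses a working hypertension
  phenotype (SBP ≥ 140 or treatment) constructed from the simulated
  covariates; the original procedure used an external GWAS cohort two
  orders of magnitude larger.
* The recalibration anchors are cohort-derived stand-ins; the original
  analysis took them from an external reference whose values are not
  printed.
* The shrinkage-based weighting that motivates the pluggable weighting
  hook (continuous-shrinkage priors over linkage panels) is out of
  scope; with linkage-free synthetic variants the marginal scheme is
  unbiased, which would not hold on real genotypes.
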