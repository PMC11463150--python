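# Methods

## The score and its conventions

The multilocus genetic score (MLGS) is an unweighted additive composite
over four dopamine-pathway variants.  Genotype classes are mapped to
per-locus scores in {0, 0.5, 1} with the low-signaling homozygote at 1
and the high-signaling homozygote at 0.  Two conventions deserve
explicit statement:

* **rs1799732 heterozygote scores 0.**  Del carriers (Ins/Del and
  Del/Del) are pooled as high-signaling, so an all-heterozygote subject
  totals 0.5 + 0 + 0.5 + 0.5 = 1.5.
* **rs6277 heterozygote is ambiguous** between an intermediate reading
  (0.5) and a T-carrier reading (1).  The package defaults to the
  intermediate rule, consistent with the general 0/0.5/1 scheme, and
  exposes `rs6277_mode: t_carrier` for the alternative.  Neither is
  asserted as the historically correct key; both are reproducible.

The dichotomization threshold is inclusive: MLGS ≥ 2.0 defines the
low-signaling group.  Scoring is strictly complete-case — a single
missing locus makes the total undefined and removes the subject from all
score-grouped analyses — while per-locus counts, allele frequencies and
Hardy–Weinberg tests use every non-missing call at that locus.  These
two denominators intentionally differ.

## Hardy–Weinberg test

Plain Pearson goodness-of-fit X² over the three genotype classes with
expected counts n·p², 2npq, n·q² (p estimated from the sample) and
df = 1; no continuity correction and no exact test.  Monomorphic loci
are flagged inapplicable with X² = 0.  Note that the four published
genotype-count triples do not all sit comfortably in HWE under this
test: the Taq1A counts (21/71/119) give X² ≈ 4.25, p ≈ 0.04.  The
package reports the computed value; it does not force agreement with
any narrative claim of equilibrium.

## Weight classes

WHO adult cut-offs with half-open intervals: normal < 25.0,
overweight [25.0, 30.0), obese ≥ 30.0 kg/m².  (Source descriptions of
the normal class as "≥ 24.9" are treated as a typographical slip for
≤ 24.9.)  BMI < 18.5 is flagged underweight but pooled with the normal
class by default — the three-class composition of the study sample sums
to ~100% — and can be split into a fourth stratum by configuration.

## Instruments

* **TFEQ-R18**: subscale score = mean of its items (1–4).  The shipped
  item→subscale map is the standard 18-item revision layout (6 CR /
  9 UE / 3 EE); it is configuration-replaceable because the instrument's
  exact item key is not part of this package's contract.  No imputation:
  a missing or out-of-range item is an error.
* **RVFQ**: percent snack choices over 12 items plus the breakpoint, the
  largest press schedule (20·k, k = 1..12) at which the snack was still
  chosen.
* **YFAS** (first version): operates on seven pre-dichotomized symptom
  indicators plus a clinical-distress indicator; diagnosis requires
  ≥ 3 symptoms (configurable) *and* distress.  The 25-item→symptom
  mapping of the original questionnaire is out of scope.

## Statistical battery

All tests are two-sided at α = 0.05 with no multiple-testing
correction (the report's manifest carries the number of tests
performed).  Mann–Whitney uses exact enumeration for tie-free pooled
samples of ≤ 16 observations and otherwise the normal approximation with
tie correction and (by default, switchable) continuity correction; an
entirely constant pooled sample returns p = 1.  Kruskal–Wallis uses the
tie-corrected H with a χ²(k−1) reference; for k = 2 its p-value is
identical to the continuity-free Mann–Whitney approximation (H = z²).
Descriptives are reported as mean ± SD even though the tests are
rank-based, mirroring the conventional table layout.  The
food-addiction 2×2 contrast defaults to Fisher's exact test (small
expected cells at realistic sample sizes), with plain Pearson χ²
available.  Correlations default to Spearman with midranks.

## Synthetic cohort generator

The generator emulates the cross-sectional study structure so every
pipeline stage is testable offline.  Defaults (all overridable):

* **Genotypes** at Hardy–Weinberg proportions with low-allele
  frequencies estimated from published counts: A1 0.268, Ins 0.859,
  T 0.615, Met 0.400; loci independent unless a haplotype-level D
  coefficient is set for the linked ANKK1/DRD2 pair.  Missing calls are
  injected completely at random at a subject-level rate of 17/221,
  mirroring the study's 221 → 204 complete-case attrition; signaling
  groups are assigned from the pre-attrition genotypes.
* **Composition**: 74% female; strata normal/overweight/obese at
  0.448 / 0.113 / 0.438.
* **Continuous phenotypes** are truncated normals per
  (stratum × signaling group) cell with the published mean ± SD
  matrices as targets.  The latent location is solved numerically so
  the *truncated* mean equals the target ("mean matching"); naive
  truncation would visibly bias variables whose mean lies within about
  one SD of a bound (e.g. trans-fat intake 0.88 ± 0.88 g at a zero
  floor).  SDs are nominal, not re-matched; truncation shrinks them
  slightly.
* **BMI intervals** per stratum are inset 0.05 kg/m² from the class
  boundaries so that weight and height written at finite precision
  re-derive the assigned class exactly; weight is back-computed as
  BMI·height² and waist as WHtR·height.
* **Emotional eating within the obesity stratum** carries an extra
  monotone dependence on the continuous MLGS via a Gaussian-copula
  latent (normal scores of jittered score ranks mixed with independent
  noise).  The mixing coefficient is found by Brent search on the
  realized Spearman correlation against the target (default 0.21,
  tolerance 0.005), using common random numbers so the objective is
  smooth and the result deterministic.  Because the group-conditional
  EE means (2.5 vs 2.9) already induce nearly the target correlation,
  the fitted coefficient is typically near zero.  An unattainable
  target raises a calibration error naming the achievable range.
* **Food addiction** is Bernoulli per (stratum × group): obesity 0.53
  (low signaling) vs 0.23 (high); the non-obese strata, for which no
  prevalence is published beyond "no group difference", default to 0.15
  in both groups — a plausible adult YFAS prevalence.  Symptom counts
  and the distress flag are back-filled so the diagnosis rule
  (≥ 3 symptoms and distress) holds exactly iff diagnosed.
* The generator emits **precomputed instrument scores** (cr/ue/ee,
  snack-choice percent, YFAS symptom count + distress) rather than raw
  item vectors; realistic inter-item covariance is not modelled.  The
  raw-item scoring paths of the pipeline are exercised by unit tests.

What passing tests on generated data do *not* show: the generator
reproduces first moments, prevalences and one targeted rank correlation,
with phenotypes otherwise conditionally independent given (stratum,
group).  Real cohorts have richer covariance (phenotype–phenotype,
genotype–stratum), measurement error and non-normal instrument
distributions; parameter-recovery results here validate the pipeline's
arithmetic and power behavior, not any biological claim.

## Problem sizes and numerics

Stochastic checks use 20,000 simulated obesity-stratum subjects
(binomial error on a prevalence ≈ 0.4 percentage points; rank
correlation calibrated to ±0.005), moment-recovery checks use the same
cohort with 4–5 σ/√n bands, and the Hardy–Weinberg recovery property
uses 300 replicate cohorts of n = 1,000 at α = 0.01.  The end-to-end
determinism contract is byte-level: a fixed (config, seed) pair yields
identical CSVs and identical rendered reports, which requires a single
seeded random stream, a fixed draw order over strata × groups ×
variables, and timestamp-free manifests.  Brent solves use xtol 1e-10
(mean matching) and 1e-5 (copula coefficient).

## Known limitations

* Subject-level results of any particular real cohort are not
  reproducible here by construction; only arithmetic derivable from
  published counts is asserted exactly.
* The empirical power of the obesity-stratum emotional-eating contrast
  at the study's group sizes (61 vs 28) is only ~0.7 at α = 0.05 under
  the configured effect size; small-cohort runs will often miss it.
* No covariate adjustment, regression modelling or multiple-testing
  correction is provided, matching the analysis design this package
  implements.
* Genotypes are handled at assay-label level; strand flips or
  sequence-level representations (VCF/PLINK) are out of scope.
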