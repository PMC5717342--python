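# Methods

## Overview

`eqtlrx` links genotype at a small set of candidate variants to (a)
genome-wide expression in a family cohort and (b) early cessation of
prescribed psychoactive medication in a register cohort. This note records
the statistical models, the defaults and why they were chosen, the design
decisions taken where the protocol was genuinely open, and what the
synthetic cohorts do and do not emulate.

## Expression arm

### Detection filter and normalization

Probes are retained when detectable (detection p ≤ 0.01) in **strictly more
than** 90% of samples; a probe detectable in exactly 90% is removed. Both
numbers are parameters (`detection_p`, `detection_frac`). Retained
intensities are quantile-normalized across samples — each rank replaced by
the across-sample mean of that rank's order statistics, ties receiving the
mean of the tied reference quantiles via average ranks — then
log2-transformed with no pseudo-count, since post-QC intensities are
strictly positive. Quantile normalization is idempotent on the intensity
scale (re-normalizing changes nothing beyond 1e-9), which the suite asserts.

### Variant inclusion

A variant is analyzable when its minor-allele-homozygote frequency — the
fraction of individuals homozygous for the rarer allele among those with
both genotype and phenotype data — meets the cut-off: 0.10 in the small
expression cohort, 0.05 in the larger register cohort (both inclusive, ≥).
This guarantees the rarest genotype class is populated. Monomorphic
variants are excluded with a logged note.

### Mixed model

Per (probe, variant): `y ~ dosage + gender + age + diagnosis` with a random
intercept per family (twin-pair ID in a twin cohort), fitted by REML
(statsmodels `MixedLM`). Dosage is additive 0/1/2 — the per-allele coding
standard for candidate-variant screens. The dosage coefficient is tested
two-sided by Wald *t* with **between-within degrees of freedom** (number of
clusters minus number of fixed effects). A calibration study during
development showed the naive normal reference mildly anti-conservative
(type-I error ≈ 0.054 at a few hundred families) because dosage varies
mostly between families while the variance components are estimated; the
between-within reference — the convention of nlme/SAS for between-cluster
covariates — restores the 5% level. Degenerate cases are explicit:

* zero dosage variance → flagged `monomorphic`, p = NA;
* zero residual variance (noiseless y) → exact coefficient, p = 0, flagged
  `degenerate_zero_residual`;
* every cluster of size one → the random intercept is unidentifiable (only
  σ² + τ² enters the likelihood) and the model reduces *exactly* to OLS,
  which is returned directly with the t(n − k) reference;
* a failed or non-converged fit is reported with a `failed` status, never
  silently dropped.

### q-values

Storey's procedure, implemented rather than wrapped: π₀(λ) =
#{p > λ}/(m(1 − λ)) on λ = 0.05, 0.10, …, 0.95, smoothed by a cubic
polynomial and evaluated at λ = 0.95; if the smoothed value is non-finite
or ≤ 0 the fixed-λ = 0.5 estimate is used; π₀ is clamped to (1/m, 1]. Then
q(i) = π₀ m p(i)/i with a cumulative minimum from the largest p downward.
With π₀ = 1 this is exactly Benjamini–Hochberg, which both the tests and
the acceptance script verify to 1e-12.

### LD and tag haplotypes

Haplotype frequencies for up to six biallelic loci are estimated by EM over
the phase ambiguity, initialized at linkage-equilibrium products (single
start for two loci; five seeded random restarts for more, since the
likelihood can be multimodal with several loci). Convergence is declared
when the largest frequency change is below 1e-10 or after 1000 iterations;
the log-likelihood is asserted non-decreasing every iteration. Individuals
missing either genotype are dropped pairwise, so each pair's `n` reflects
those genotyped at both loci. D′ uses the sign-dependent bound
(min(p_A p_b, p_a p_B) for D > 0, min(p_A p_B, p_a p_b) otherwise); r² is
flagged undefined at boundary allele frequencies.

A multi-SNP tag haplotype is converted to a per-individual dosage as the
posterior expected copy number of the target haplotype given the unphased
genotype under the EM frequencies (fractional by default; a rounded
hard-assignment is also returned). Posterior dosage is preferred because it
propagates phase uncertainty into the downstream regression instead of
fabricating certainty.

### Replication tallies and enrichment

Probes nominally significant in discovery (p ≤ 0.05, pre-FDR) are checked
against three sources: a high-LD partner variant in the same cohort, an
independent twin cohort (probe-level), and an external gene-keyed result
table (gene-symbol match, direction ignored by default since external
databases report significance; a same-direction mode exists behind a flag).
Probes lacking an official gene symbol are excluded from external matching
and reported in a coverage tally. Summary counts are monotone by
construction (≥1 ⊇ ≥2 ⊇ =3) and gene counts never exceed probe counts.

Enrichment of a significant gene set for predicted microRNA targets (≥ 6 of
12 prediction programs) is the one-sided hypergeometric tail. The universe
is the set of genes actually tested in the screen, not the genome:
enrichment must condition on testability. Probe-level and gene-level
enrichment are both supported.

## Medication arm

### Exposure episodes

Dates are integer day offsets from a configurable epoch (ISO-8601 in
files); intervals are half-open. Each purchase supplies `ddd_amount × 1.1`
days. A purchase made before the current supply ends starts when it ends
(carry-over — the standard reading in the exposure-episode literature,
where stockpiled supply is consumed after the current package). Successive
supply intervals separated by ≤ 15 days are bridged into one episode, and
the bridged days count toward its duration. Construction is order-invariant
and matches a brute-force day-grid simulation on 1000 random registers (an
acceptance check).

Episodes whose supply runs past the observation-window end are flagged
censored and excluded from cessation outcomes: their true duration is
unknown (right-censoring guard).

### Outcomes, filters, groups

Early cessation is `duration ≤ 90 days`, inclusive — "three months" is
fixed at 90 days for determinism, with the cut-off a parameter so a 91-day
(calendar) reading changes only boundary instances. An alternative outcome
mode — no repurchase of *any* drug within 90 days of the episode start — is
provided (`derive_cessation_repurchase`) but is not the default; the
duration-based reading is the primary analysis. Single-drug analyses
require ≥ 15 early-cessation instances (the filter counts instances of use
for three months or less, not all episodes); group analyses pool all mapped
drugs regardless of frequency, over the five groups: CYP2C19-metabolized,
SSRI, SSRI∩CYP2C19, SSRI∖CYP2C19, non-SSRI∩CYP2C19. The drug → group map is
a plain TSV and fully configurable.

### GEE

`cessation ~ dosage + gender (+ dosage × gender)`, Binomial logistic
marginal model clustered by individual, **exchangeable** working
correlation (repeated episodes of one person are exchangeable a priori;
independence is available by flag and the suite verifies both give the same
estimates to 1e-3 when outcomes are truly independent), robust sandwich
standard errors, Wald 95% CIs on the log-odds scale with no small-sample
correction. Gender is kept in the main-effects model by default. With
singleton clusters the estimates coincide with ordinary logistic ML and
HC0-robust SEs to 1e-6 (asserted). Bonferroni thresholds are per screen:
α/(number of drugs tested) and α/(number of groups), e.g. 0.05/24 ≈ 0.0021
and 0.05/5 = 0.01.

## Synthetic cohorts

The generator (`synthdata`) is first-class, tested code; its defaults are
the study conditions the rest of the package is validated under.

* **Genotypes.** Nuclear families (default sizes 2–6): two founders draw
  haplotype pairs from the configured two-locus haplotype frequencies;
  offspring inherit one unrecombined haplotype per parent (Mendelian
  consistency is asserted). The default frequencies put allele frequency
  0.35 at both loci with population r² = 0.88 — strong LD typical of tag
  SNPs in one block, and a minor-homozygote frequency (~12%) that passes
  the 10% inclusion cut-off. `haplotype_freqs_for_r2` solves for
  frequencies at any requested r². Four-locus haplotype vectors (16
  frequencies) generate tag-haplotype test data.
* **Expression.** log2-scale: probe baseline N(8, 1) + β·dosage on the true
  eQTL probes + covariate effects (gender 0.10, age 0.002/yr, diagnosis
  0.10 — small, realistic nuisance effects) + family intercept N(0, 0.25²)
  + noise N(0, 0.53²). The canonical effect size is β = 0.52 with residual
  sd 0.53 (effect ≈ 1 residual sd, a large regulatory effect). Raw
  intensities are 2^y. Detection p-values are Beta(1, 500) for expressed
  probes and Uniform(0, 1) for a configurable fraction (default 15%) of
  null probes, which therefore fail the >90% filter — only the filter's
  behaviour is modelled, not array physics.
* **Target predictions.** Target status (≥ k of 12 programs) is Bernoulli
  with base rate 2588/16027 ≈ 0.16 (realistic aggregate-database margins),
  with the odds multiplied by the configured enrichment odds ratio (default
  3) for true eQTL genes; given the status, the program count is drawn
  above or below k and assigned to a random program subset.
* **Purchases.** Over a 10-year window (365-day years, 30-day months),
  affected individuals (default fraction 23/64, an ascertained-cohort
  ratio) use each drug with a per-drug probability tuned to produce
  group sizes of a few hundred instances at ~650 families. Early cessation
  follows logit(p) = logit(0.35) + ln(OR_g)·g + ln(OR_sex)·sex +
  ln(OR_int)·g·sex. The default drug panel has 7 CYP2C19 drugs (4 SSRIs),
  2 non-CYP2C19 SSRIs and 2 others, with default effects: interaction OR
  0.30 for SSRI∩CYP2C19, 4.93 for non-SSRI∩CYP2C19, and a genotype main
  effect OR 4.13 for one antipsychotic. Early users make one purchase
  (stretched supply ≤ 78 days); continuing users refill 30-DDD purchases
  with gaps ≤ 12 days for at least four fills, and episode starts leave a
  600-day margin before the window end so continuing episodes are never
  censored. The base early-cessation probability 0.35 reflects the high
  early discontinuation typical of psychoactive prescribing.

The same seed yields byte-identical cohorts. What the generator does *not*
emulate: array background/batch effects, recombination, ascertainment of
the register, drug switching, dose titration, and any correlation between
expression and medication outcomes beyond their shared genotype.

## Problem sizes used in validation

Chosen as the package's own validation design: the mixed-model null
calibration uses 2000 probes on 160 families of 2–6 (~640 individuals) —
large enough that the between-within t reference is accurate and the
binomial noise on the rejection fraction is ~0.005; LD recovery uses 1891
individuals genotyped at both loci; GEE coverage uses 500 register
replicates of ~440 instances each; the episode oracle runs 1000 random
registers; hypergeometric/Fisher agreement uses 10 000 random tables. The
end-to-end demo configuration (60 families, 150 probes) is sized to run the
whole pipeline, twin replication included, in well under a minute per run.

## Known limitations

* The screen refits the mixed model per probe through statsmodels; at
  microarray scale (~12 000 probes) a full screen takes tens of minutes on
  one core. No trans/cis distinction or conditional analysis is attempted.
* π₀ smoothing uses a cubic polynomial rather than a spline; on the λ grid
  used the two are indistinguishable in practice, and the fixed-λ fallback
  guards pathological inputs.
* The EM phasing is exact only in the sense of maximum likelihood under
  Hardy–Weinberg at the haplotype level; family structure is ignored when
  phasing (as in standard LD software), which is harmless for LD summaries
  but means posterior tag dosages do not exploit pedigree information.
* GEE Wald CIs carry no small-sample correction; with few clusters they
  can undercover.
* Calendar-month episode arithmetic (true month lengths) applies only to
  real-date inputs through the I/O layer; simulation uses 30-day months.
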