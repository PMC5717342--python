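# eqtlrx

Family-cohort eQTL screening with multi-source replication and microRNA
target enrichment, plus prescription-register pharmacogenetics of early
medication cessation.

## The scientific problem

Candidate risk loci for psychiatric illness can act by changing gene
expression genome-wide — for example through a microRNA encoded within the
locus — and such regulatory effects may in turn change how patients respond
to psychoactive medication metabolized by particular enzymes. Testing this
chain needs two very different data types analyzed coherently:

1. **Expression arm.** Microarray expression in a *family* cohort, where
   relatedness must enter the model, screened probe-by-probe against
   candidate SNPs, with FDR control, internal replication through variants
   in high linkage disequilibrium (LD), replication in an independent
   cohort and in an external eQTL database, and enrichment of the hit list
   for predicted microRNA targets.
2. **Medication arm.** National prescription-register purchase records
   (dates and amounts in defined daily doses, DDD) converted into drug
   exposure episodes, a binary *early cessation* outcome (episode lasting
   three months or less), and genotype × gender interaction models fitted
   by GEE because one person contributes many episodes.

`eqtlrx` implements both arms as a tested, reusable pipeline. Because the
family data such studies use are protected, the package ships a
synthetic-cohort generator with known ground truth (pedigree-dropped
two-locus haplotypes, additive expression effects, family random
intercepts, configurable target-enrichment odds ratios, and purchase
histories whose cessation probability follows a logistic genotype × gender
model), so that every stage is verifiable end to end.

## Models and statistics

**Mixed-model eQTL screen.** For probe expression *y* (quantile-normalized,
log2) and allele dosage *g* ∈ {0, 1, 2}:

    y_ij = β0 + β1 g_ij + β2 sex_ij + β3 age_ij + β4 dx_ij + u_j + ε_ij,
    u_j ~ N(0, τ²) per family,  ε_ij ~ N(0, σ²)

fitted by REML; the dosage effect β1 is tested by a Wald *t* test with
between-within degrees of freedom. Variants enter only if the
minor-allele-homozygote frequency is ≥ 10% (expression arm) or ≥ 5%
(register arm). FDR uses Storey q-values: π₀ is estimated by the
Storey–Tibshirani smoother and q(i) = π₀ · m · p(i)/i with monotonicity
enforcement (π₀ = 1 reproduces Benjamini–Hochberg exactly).

**LD.** Two-locus (up to six-locus) haplotype frequencies by EM over the
phase ambiguity; D = p_AB − p_A p_B, D′ = |D|/D_max, r² = D²/(p_A p_a p_B p_b).
A multi-SNP tag haplotype becomes an analyzable dosage via its posterior
expected copy number per individual.

**Enrichment.** Genes predicted as microRNA targets by at least 6 of 12
programs form the target set; over-representation among significant genes
is the one-sided hypergeometric tail P(X ≥ overlap), conditioned on the
genes actually tested.

**Exposure episodes.** Each purchase supplies DDD × 1.1 days; supply bought
early is appended after the current supply (carry-over); gaps of ≤ 15 days
between supply intervals are bridged. An episode of ≤ 90 days is an early
cessation. Drugs with ≥ 15 early-cessation instances are tested singly;
enzyme/class groups (CYP2C19-metabolized, SSRI, and their intersections /
differences) pool all drugs.

**GEE.** cessation ~ dosage + gender (+ dosage × gender), Binomial logistic
marginal model, clustered by individual, exchangeable working correlation,
robust sandwich CIs; Bonferroni thresholds of α/24 ≈ 0.0021 for single-drug
screens and α/5 = 0.01 for group screens.

## Worked example

```python
from eqtlrx import (CohortSpec, generate_genotypes, generate_covariates,
                    generate_expression, generate_purchases, fit_probe,
                    ld_between, build_episodes, derive_cessation,
                    group_instances, gee_fit)

spec = CohortSpec(n_families=200, n_probes=50, n_true_eqtl=10, seed=42)
gt = generate_genotypes(spec)
cov = generate_covariates(gt, spec)

ld = ld_between(gt.dosages["snp1"], gt.dosages["snp2"])
print(f"LD between snp1 and snp2: r2 = {ld.r2:.3f}, D' = {ld.D_prime:.3f}, n = {ld.n}")

expr = generate_expression(gt, cov, spec)
probe = expr.true_probes[0]
res = fit_probe(expr.log2.loc[probe], gt.dosages["snp1"], cov, probe_id=probe)
print(f"{probe}: beta = {res.beta:.3f} (se {res.se:.3f}), p = {res.p:.2e}")
```

prints

```
LD between snp1 and snp2: r2 = 0.890, D' = 0.965, n = 780
probe00004: beta = 0.564 (se 0.032), p = 2.03e-42
```

The default cohort generates the two SNPs in strong LD (population
r² = 0.88; the sample estimate here is 0.890 over 780 individuals), and the
first true eQTL probe recovers an effect near the generating 0.52 log2
units per allele. Scaling the same cohort to register size (650 families)
and running the medication arm:

```python
spec = CohortSpec(n_families=650, seed=42)
gt = generate_genotypes(spec); cov = generate_covariates(gt, spec)
reg = generate_purchases(gt, cov, spec)
eps = build_episodes(reg.register, window_end=spec.window_days)
inst = derive_cessation(eps, covariates=cov, genotypes=gt.dosages,
                        drug_map=reg.drug_map)
grp = group_instances(inst, reg.drug_map)["non_ssri_cyp2c19"]
fit = gee_fit(grp, "snp1", model="interaction", outcome_label="non_ssri_cyp2c19")
print(f"non-SSRI/CYP2C19 group: interaction OR = {fit.or_interaction:.2f} "
      f"(95% CI {fit.ci_interaction[0]:.2f}-{fit.ci_interaction[1]:.2f}), "
      f"p = {fit.p_interaction:.1e}, instances = {fit.n_instances}")
```

prints

```
non-SSRI/CYP2C19 group: interaction OR = 6.00 (95% CI 3.22-11.18), p = 1.7e-08, instances = 437
```

i.e. the genotype-by-gender interaction built into the generator for
non-SSRI CYP2C19-metabolized drugs (odds ratio 4.93) is detected, with the
truth inside the 95% CI, on a cohort of 437 exposure instances.

The whole chain — simulate → QC → eQTL → LD → replication → enrichment →
episodes → GEE — runs from one config:

```sh
eqtlrx run-all --config configs/demo.yaml
```

which writes the generated inputs, all stage outputs and a reproducibility
manifest under `results/demo/`. Individual stages are available as
subcommands (`simulate`, `qc`, `eqtl`, `ld`, `replicate`, `enrich`,
`episodes`, `pharmaco`).

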