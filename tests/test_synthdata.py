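"""Ground-truth properties of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from eqtlrx import synthdata as sd
from eqtlrx.eqtl import fit_probe
from eqtlrx.exprqc import detection_filter
from eqtlrx.ld import ld_between
from eqtlrx.medication import build_episodes, derive_cessation


def test_spec_validation():
    with pytest.raises(ValueError, match="summing to 1"):
        sd.CohortSpec(haplotype_freqs=(0.5, 0.2, 0.2, 0.2))
    with pytest.raises(ValueError, match="power of 2"):
        sd.CohortSpec(haplotype_freqs=(0.5, 0.3, 0.2))
    with pytest.raises(ValueError, match="n_true_eqtl"):
        sd.CohortSpec(n_probes=5, n_true_eqtl=6)
    with pytest.raises(ValueError, match="family sizes"):
        sd.CohortSpec(family_size_range=(1, 4))


def test_same_seed_identical_output(small_spec):
    a = sd.generate_cohort(small_spec)
    b = sd.generate_cohort(small_spec)
    pd.testing.assert_frame_equal(a["genotypes"].dosages, b["genotypes"].dosages)
    pd.testing.assert_frame_equal(a["covariates"], b["covariates"])
    pd.testing.assert_frame_equal(a["expression"].log2, b["expression"].log2)
    pd.testing.assert_frame_equal(a["targets"], b["targets"])
    pd.testing.assert_frame_equal(a["purchases"].register, b["purchases"].register)


def test_founder_haplotypes_follow_multinomial():
    spec = sd.CohortSpec(n_families=400, seed=21)
    gt = sd.generate_genotypes(spec)
    founders = gt.haplotypes.loc[gt.meta["is_founder"]]
    counts = np.bincount(
        np.concatenate([founders["hap1"], founders["hap2"]]), minlength=4
    )
    _, p = chisquare(counts, f_exp=np.array(spec.haplotype_freqs) * counts.sum())
    assert p > 0.001


def test_mendelian_consistency():
    spec = sd.CohortSpec(n_families=100, family_size_range=(3, 6), seed=22)
    gt = sd.generate_genotypes(spec)
    haps = gt.haplotypes
    for ind, row in gt.meta.loc[~gt.meta["is_founder"]].iterrows():
        child = set(haps.loc[ind])
        parental = set(haps.loc[row["father_id"]]) | set(haps.loc[row["mother_id"]])
        assert child <= parental


def test_complete_ld_and_equilibrium_extremes():
    # (0.5, 0, 0, 0.5): every individual identical at both loci, r2 = 1
    spec = sd.CohortSpec(haplotype_freqs=(0.5, 0.0, 0.0, 0.5), n_families=100, seed=23)
    gt = sd.generate_genotypes(spec)
    assert (gt.dosages["snp1"] == gt.dosages["snp2"]).all()
    assert ld_between(gt.dosages["snp1"], gt.dosages["snp2"]).r2 == pytest.approx(1.0)
    # (0.25 x 4): linkage equilibrium, sample r2 near 0 at large n
    spec = sd.CohortSpec(haplotype_freqs=(0.25,) * 4, n_families=1500, seed=24)
    gt = sd.generate_genotypes(spec)
    assert ld_between(gt.dosages["snp1"], gt.dosages["snp2"]).r2 < 0.01


def test_degenerate_noise_gives_covariate_determined_values():
    spec = sd.CohortSpec(
        n_families=10, n_probes=3, n_true_eqtl=0, eqtl_effect=0.0,
        family_sd=0.0, residual_sd=0.0, seed=25,
    )
    gt = sd.generate_genotypes(spec)
    cov = sd.generate_covariates(gt, spec)
    expr = sd.generate_expression(gt, cov, spec)
    eff = spec.covariate_effects
    cov_term = (
        eff.gender * cov["gender"] + eff.age * cov["age"] + eff.diagnosis * cov["diagnosis"]
    )
    resid = expr.log2.sub(cov_term, axis=1)
    # all samples of a probe collapse to the probe baseline
    assert (resid.std(axis=1) < 1e-12).all()


def test_eqtl_effect_recovered_at_canonical_setting():
    """Fitted dosage effects on true probes average the generating 0.52
    within +/- 0.05 (residual sd 0.53)."""
    spec = sd.CohortSpec(n_families=120, n_probes=60, n_true_eqtl=60, seed=26)
    gt = sd.generate_genotypes(spec)
    cov = sd.generate_covariates(gt, spec)
    expr = sd.generate_expression(gt, cov, spec)
    betas = [
        fit_probe(expr.log2.loc[p], gt.dosages["snp1"], cov).beta
        for p in expr.true_probes
    ]
    assert np.mean(betas) == pytest.approx(0.52, abs=0.05)


def test_detection_pvalues_drive_filter(small_cohort):
    expr = small_cohort["expression"]
    kept = detection_filter(expr.matrix)
    assert set(expr.undetected_probes).isdisjoint(kept.probe_ids)
    assert set(expr.true_probes) <= set(kept.probe_ids)


def test_target_matrix_realizes_requested_odds_ratio(rng):
    """At an enrichment odds ratio of 3 with realistic margins (~16% of
    16 027 genes targets), the realized 2x2 odds ratio is within 20%."""
    genes = [f"G{i}" for i in range(16027)]
    true = set(rng.choice(genes, 2500, replace=False))
    spec = sd.CohortSpec(target_enrichment_or=3.0, seed=27)
    m = sd.generate_target_matrix(genes, true, spec, rng=np.random.default_rng(27))
    is_target = (m.sum(axis=1) >= spec.target_k)
    t = pd.Series(is_target.to_numpy(), index=m.index)
    in_true = pd.Index(genes).isin(true)
    a = (t.to_numpy() & in_true).sum()
    b = (~t.to_numpy() & in_true).sum()
    c = (t.to_numpy() & ~in_true).sum()
    d = (~t.to_numpy() & ~in_true).sum()
    realized = (a * d) / (b * c)
    assert 0.8 * 3 <= realized <= 1.2 * 3
    # total target fraction near the configured base rate
    assert t.mean() == pytest.approx(2588 / 16027, abs=0.05)


def test_target_matrix_extreme_or_makes_all_true_genes_targets(rng):
    genes = [f"G{i}" for i in range(500)]
    true = set(genes[:60])
    spec = sd.CohortSpec(target_enrichment_or=np.inf, seed=28)
    m = sd.generate_target_matrix(genes, true, spec, rng=np.random.default_rng(28))
    assert (m.loc[sorted(true)].sum(axis=1) >= spec.target_k).all()


def test_purchase_truth_matches_derived_outcomes():
    """Every simulated episode's ground-truth early flag is reproduced by the
    episode construction + cut-off chain (33 = 30 x 1.1-day rule included)."""
    spec = sd.CohortSpec(n_families=150, seed=29)
    gt = sd.generate_genotypes(spec)
    cov = sd.generate_covariates(gt, spec)
    reg = sd.generate_purchases(gt, cov, spec)
    eps = build_episodes(reg.register, window_end=spec.window_days)
    inst = derive_cessation(eps)
    merged = reg.truth.merge(
        inst[["individual_id", "atc_code", "early_cessation"]],
        on=["individual_id", "atc_code"],
    )
    assert len(merged) == len(reg.truth)
    assert (merged["early"].astype(int) == merged["early_cessation"]).all()


def test_null_generator_gives_uniform_downstream_pvalues():
    """With all drug effects at OR 1, GEE interaction p-values are null:
    the CI covers 1 in >= 90% of replicates."""
    from eqtlrx.medication import group_instances
    from eqtlrx.pharmacogee import gee_fit

    null_drugs = tuple(
        sd.DrugSpec(f"D{k}", bool(k % 2), True, use_prob=0.5) for k in range(4)
    )
    covered = 0
    n_rep = 30
    for rep in range(n_rep):
        spec = sd.CohortSpec(n_families=120, drugs=null_drugs, seed=1000 + rep)
        gt = sd.generate_genotypes(spec)
        cov = sd.generate_covariates(gt, spec)
        reg = sd.generate_purchases(gt, cov, spec)
        eps = build_episodes(reg.register, window_end=spec.window_days)
        inst = derive_cessation(eps, covariates=cov, genotypes=gt.dosages,
                                drug_map=reg.drug_map)
        grp = group_instances(inst, reg.drug_map)["cyp2c19_all"]
        fit = gee_fit(grp, "snp1", model="interaction")
        if fit.ci_interaction[0] <= 1 <= fit.ci_interaction[1]:
            covered += 1
    assert covered >= 0.9 * n_rep - 2  # 3 binomial SDs of slack at n=30
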