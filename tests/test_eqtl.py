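"""Variant selection, the mixed-model probe fit, and Storey q-values."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from eqtlrx import synthdata as sd
from eqtlrx.eqtl import fit_probe, qvalues, run_screen, select_variants


def _dosage_frame(counts: dict[int, int]) -> pd.DataFrame:
    """Column 'v' with `counts[d]` individuals at dosage d."""
    vals = sum(([float(d)] * n for d, n in counts.items()), [])
    return pd.DataFrame({"v": vals}, index=[f"i{k}" for k in range(len(vals))])


@pytest.mark.parametrize(
    "n_hom, cutoff, kept",
    [(4, 0.10, True),   # 4/39 = 10.3% >= 10%
     (3, 0.10, False),  # 3/39 = 7.7% < 10%
     (3, 0.05, True)],  # but kept at the 5% register-arm cut-off
)
def test_select_variants_minor_hom_frequency(n_hom, cutoff, kept):
    d = _dosage_frame({2: n_hom, 1: 15, 0: 39 - 15 - n_hom})
    assert (select_variants(d, cutoff) == ["v"]) is kept


def test_select_variants_all_het_and_monomorphic_excluded():
    assert select_variants(_dosage_frame({1: 30}), 0.01) == []
    assert select_variants(_dosage_frame({2: 30}), 0.01) == []


def _singleton_cov(rng, n):
    return pd.DataFrame(
        {
            "gender": rng.integers(0, 2, n).astype(float),
            "age": rng.integers(18, 70, n).astype(float),
            "diagnosis": rng.integers(0, 2, n).astype(float),
            "family_id": [f"f{k}" for k in range(n)],
        },
        index=[f"i{k}" for k in range(n)],
    )


def test_fit_probe_noiseless_degenerate(rng):
    cov = _singleton_cov(rng, 60)
    g = rng.integers(0, 3, 60).astype(float)
    res = fit_probe(2.0 * g, g, cov)
    assert res.beta == pytest.approx(2.0, abs=1e-8)
    assert res.status == "degenerate_zero_residual"
    assert res.p == 0.0


def test_fit_probe_singleton_families_equals_ols(rng):
    """With one individual per family the mixed model reduces to OLS:
    beta, se and Wald p agree with the closed form to 1e-6."""
    n = 150
    cov = _singleton_cov(rng, n)
    g = rng.integers(0, 3, n).astype(float)
    y = 0.4 * g + 0.1 * cov["gender"].to_numpy() + rng.normal(0, 0.5, n)
    res = fit_probe(y, g, cov)
    X = np.column_stack([np.ones(n), g, cov["gender"], cov["age"], cov["diagnosis"]])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    s2 = np.sum((y - X @ beta) ** 2) / (n - X.shape[1])
    se = float(np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1]))
    p = float(2 * t_dist.sf(abs(beta[1] / se), df=n - X.shape[1]))
    assert res.beta == pytest.approx(beta[1], rel=1e-6)
    assert res.se == pytest.approx(se, rel=1e-6)
    assert res.p == pytest.approx(p, rel=1e-6)


def test_fit_probe_constant_dosage_flagged(rng):
    cov = _singleton_cov(rng, 30)
    res = fit_probe(rng.normal(size=30), np.ones(30), cov)
    assert res.status == "monomorphic" and np.isnan(res.p)


def test_qvalues_tiny_pvalues_all_significant():
    p = np.full(100, 1e-9)
    q, pi0 = qvalues(p)
    assert (q <= 1e-7).all()
    assert (q <= 0.05).all()


def test_qvalues_equal_bh_when_pi0_forced_to_one(rng):
    p = rng.random(500)
    q, _ = qvalues(p, pi0=1.0)
    bh = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(q, bh, atol=1e-12)


def test_qvalues_pi0_near_one_under_uniform_null(rng):
    p = rng.random(10000)
    _, pi0 = qvalues(p)
    assert 0.9 <= pi0 <= 1.1


def test_qvalues_rejects_bad_input():
    with pytest.raises(ValueError):
        qvalues([0.5] * 5)
    with pytest.raises(ValueError):
        qvalues(np.concatenate([np.full(20, 0.5), [1.5]]))


def test_qvalues_order_consistent_with_p(rng):
    p = rng.random(200)
    q, _ = qvalues(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()


@pytest.fixture(scope="module")
def screen(small_cohort):
    gt = small_cohort["genotypes"]
    cov = small_cohort["covariates"]
    expr = small_cohort["expression"]
    res, summary = run_screen(
        expr.log2, gt.dosages, cov, ["snp1"], annotation=expr.annotation
    )
    return small_cohort, res, summary


class TestRunScreen:
    def test_gene_counts_never_exceed_probe_counts(self, screen):
        _, _, summary = screen
        s = summary["snp1"]
        assert s["n_genes_p"] <= s["n_probes_p"]
        assert s["n_genes_q"] <= s["n_probes_q"]

    def test_probes_sharing_a_gene_counted_once(self, small_cohort):
        """Two significant probes mapping to one gene -> gene count 1, probe count 2."""
        gt = small_cohort["genotypes"]
        cov = small_cohort["covariates"]
        g = gt.dosages["snp1"]
        rng = np.random.default_rng(0)
        strong = pd.DataFrame(
            {s: [3.0 * g[s] + rng.normal(0, 0.05), 3.0 * g[s] + rng.normal(0, 0.05)]
             for s in gt.individuals},
            index=["pa", "pb"],
        )
        ann = pd.Series(["SHARED", "SHARED"], index=["pa", "pb"])
        _, summary = run_screen(strong, gt.dosages, cov, ["snp1"], annotation=ann)
        # q-values need >= 10 p-values so only probe-level p counts apply here
        assert summary["snp1"]["n_probes_p"] == 2
        assert summary["snp1"]["n_genes_p"] == 1

    def test_zero_variants_exits_cleanly(self, small_cohort):
        expr = small_cohort["expression"]
        res, summary = run_screen(
            expr.log2, small_cohort["genotypes"].dosages,
            small_cohort["covariates"], [],
        )
        assert res.empty and summary == {}

    def test_joint_permutation_leaves_results_identical(self, screen):
        cohort, res, _ = screen
        gt, cov, expr = cohort["genotypes"], cohort["covariates"], cohort["expression"]
        perm = np.random.default_rng(1).permutation(expr.log2.shape[1])
        cols = expr.log2.columns[perm]
        res2, _ = run_screen(
            expr.log2[cols], gt.dosages, cov, ["snp1"], annotation=expr.annotation
        )
        np.testing.assert_allclose(res["p"], res2["p"], rtol=1e-8)

    def test_breaking_genotype_link_destroys_association(self, small_cohort):
        """Permuting expression against genotype on a strong-effect fixture
        pushes the median p above 0.3."""
        gt, cov = small_cohort["genotypes"], small_cohort["covariates"]
        g = gt.dosages["snp1"].to_numpy()
        rng = np.random.default_rng(2)
        probes = {f"p{k}": 2.0 * g + rng.normal(0, 0.3, g.size) for k in range(40)}
        strong = pd.DataFrame(probes, index=gt.individuals).T
        res, _ = run_screen(strong, gt.dosages, cov, ["snp1"])
        assert res["p"].median() < 1e-6
        shuf = strong.copy()
        for k in range(shuf.shape[0]):  # independent permutation per probe
            shuf.iloc[k] = strong.iloc[k].to_numpy()[rng.permutation(g.size)]
        res_perm, _ = run_screen(shuf, gt.dosages, cov, ["snp1"])
        assert res_perm["p"].median() > 0.3
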