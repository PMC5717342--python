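"""Per-probe mixed-model eQTL screen with Storey q-value FDR.

For each (probe, variant) pair, expression is regressed on allele dosage
(additive 0/1/2 coding) with gender, age and diagnostic status as fixed
covariates and a random intercept per family (twin-pair ID plays the same
role in a twin cohort):

    y_ij = b0 + b1 * dosage_ij + b2 * gender + b3 * age + b4 * diagnosis
           + u_j + e_ij,   u_j ~ N(0, tau^2), e_ij ~ N(0, sigma^2)

fitted by REML; the dosage coefficient is tested with a two-sided Wald test
against a t reference with between-within degrees of freedom (number of
clusters minus number of fixed effects), the standard small-sample choice
for covariates that vary mostly between clusters.
Genome-wide significance is assessed by Storey's q-value procedure with the
proportion of true nulls (pi0) estimated from the p-value distribution.

Variants enter the screen only if their minor-allele-homozygote frequency —
the fraction of individuals homozygous for the rarer allele — meets a
cut-off (10% in a small expression cohort, 5% in a larger register cohort),
which guarantees all three genotype classes are populated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

__all__ = [
    "VariantFilterSpec",
    "EqtlResult",
    "select_variants",
    "fit_probe",
    "qvalues",
    "run_screen",
]

logger = logging.getLogger(__name__)


@dataclass
class VariantFilterSpec:
    """Minor-allele-homozygote frequency cut-off for variant inclusion."""

    min_minor_hom_freq: float = 0.10
    arm: str = "expression"  # "expression" (10%) or "medication" (5%)

    def __post_init__(self) -> None:
        if not 0 <= self.min_minor_hom_freq <= 0.5:
            raise ValueError("min_minor_hom_freq must be in [0, 0.5]")


@dataclass
class EqtlResult:
    """Association of one probe with one variant."""

    probe_id: str
    variant_id: str
    beta: float
    se: float
    p: float
    q: float = float("nan")
    n_used: int = 0
    status: str = "ok"  # ok | monomorphic | degenerate_zero_residual | failed


def select_variants(
    dosages: pd.DataFrame,
    spec: VariantFilterSpec | float = 0.10,
    samples: pd.Index | list | None = None,
) -> list[str]:
    """Variants whose minor-allele-homozygote frequency meets the cut-off.

    ``dosages`` is individuals x variants; ``samples`` restricts the count
    to individuals with both genotype and phenotype data.  The cut-off is
    inclusive (>=).  Monomorphic variants are excluded (logged).
    """
    cutoff = spec.min_minor_hom_freq if isinstance(spec, VariantFilterSpec) else float(spec)
    d = dosages if samples is None else dosages.loc[dosages.index.intersection(samples)]
    kept = []
    for var in d.columns:
        g = d[var].dropna().to_numpy()
        if g.size == 0:
            continue
        p1 = g.mean() / 2  # frequency of the counted allele
        if p1 <= 0 or p1 >= 1:
            logger.info("variant %s is monomorphic; excluded", var)
            continue
        minor_hom = 2 if p1 <= 0.5 else 0
        freq = (g == minor_hom).mean()
        if freq >= cutoff:
            kept.append(var)
    return kept


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return beta, rss


def fit_probe(
    y: np.ndarray | pd.Series,
    dosage: np.ndarray | pd.Series,
    cov: pd.DataFrame,
    probe_id: str = "",
    variant_id: str = "",
) -> EqtlResult:
    """Mixed-model association of one probe with one variant.

    ``cov`` must carry ``gender``, ``age``, ``diagnosis`` and ``family_id``
    rows aligned with ``y`` and ``dosage``.  Rows with any missing value are
    dropped.  Returns a flagged result (p = NaN) rather than raising when
    the dosage is constant or the fit fails.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(dosage, dtype=float)
    X = np.column_stack(
        [
            np.ones_like(y),
            g,
            cov["gender"].to_numpy(dtype=float),
            cov["age"].to_numpy(dtype=float),
            cov["diagnosis"].to_numpy(dtype=float),
        ]
    )
    groups = cov["family_id"].to_numpy()
    ok = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    y, X, groups = y[ok], X[ok], groups[ok]
    n = y.size

    if n < X.shape[1] + 1 or np.var(X[:, 1]) == 0:
        return EqtlResult(probe_id, variant_id, np.nan, np.nan, np.nan, n_used=n,
                          status="monomorphic")

    beta_ols, rss = _ols(y, X)
    tss = float(np.sum((y - y.mean()) ** 2))
    if rss <= 1e-12 * max(tss, 1.0):
        # noiseless data: effect recovered exactly, p degenerates to 0
        return EqtlResult(probe_id, variant_id, float(beta_ols[1]), 0.0, 0.0,
                          n_used=n, status="degenerate_zero_residual")

    if pd.Series(groups).value_counts().max() == 1:
        # one individual per cluster: the random intercept is unidentifiable
        # (only sigma^2 + tau^2 enters the likelihood) and the mixed model
        # reduces exactly to OLS
        s2 = rss / (n - X.shape[1])
        se = float(np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1]))
        p = float(2 * t_dist.sf(abs(beta_ols[1] / se), df=n - X.shape[1]))
        return EqtlResult(probe_id, variant_id, float(beta_ols[1]), se, p, n_used=n)

    from statsmodels.regression.mixed_linear_model import MixedLM

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(y, X, groups=groups)
            res = model.fit(reml=True)
        beta = float(res.params[1])
        se = float(res.bse[1])
        if not np.isfinite(se) or se <= 0:
            raise ValueError("non-finite standard error")
        # between-within df: clusters minus fixed effects
        df = max(len(np.unique(groups)) - X.shape[1], 1)
        p = float(2 * t_dist.sf(abs(beta / se), df=df))
        return EqtlResult(probe_id, variant_id, beta, se, p, n_used=n)
    except Exception as exc:  # noqa: BLE001 - flagged, never silently dropped
        logger.warning("fit failed for probe %s / variant %s: %s", probe_id, variant_id, exc)
        return EqtlResult(probe_id, variant_id, np.nan, np.nan, np.nan, n_used=n,
                          status="failed")


def qvalues(
    p: np.ndarray | list,
    pi0: float | None = None,
    lambdas: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Storey q-values and the pi0 estimate.

    pi0 is estimated by the Storey–Tibshirani smoother: pi0(lambda) =
    #{p > lambda} / (m (1 - lambda)) on a lambda grid 0.05..0.95, smoothed
    with a cubic polynomial and read off at the largest lambda.  If the
    smoothed value is unstable (<= 0 or non-finite), the fixed lambda = 0.5
    point estimate is used instead.  Forcing ``pi0=1`` reproduces
    Benjamini–Hochberg adjusted p-values exactly.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 10:
        raise ValueError("need at least 10 p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size

    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.951, 0.05)
        pi0_lam = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
        try:
            coef = np.polyfit(lambdas, pi0_lam, deg=3)
            pi0_hat = float(np.polyval(coef, lambdas.max()))
        except Exception:  # noqa: BLE001
            pi0_hat = float("nan")
        if not np.isfinite(pi0_hat) or pi0_hat <= 0:
            pi0_hat = float((p > 0.5).sum() / (m * 0.5))
        pi0 = min(max(pi0_hat, 1.0 / m), 1.0)

    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0, 1)
    q = np.empty(m)
    q[order] = q_sorted
    return q, float(pi0)


def run_screen(
    expression: pd.DataFrame,
    dosages: pd.DataFrame,
    cov: pd.DataFrame,
    variants: list[str] | None = None,
    annotation: pd.Series | None = None,
    alpha: float = 0.05,
    q_thresh: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Fit every probe x variant pair and summarize significance counts.

    ``expression`` is probes x samples (normalized log2), ``dosages``
    individuals x variants, ``cov`` indexed by individual.  Counts are
    reported per variant at p <= alpha and q <= q_thresh, at probe level
    and — via ``annotation`` (probe -> gene symbol) — at distinct-gene
    level.  Probes without annotation contribute to probe counts only.
    """
    if variants is None:
        variants = list(dosages.columns)
    samples = expression.columns.intersection(cov.index).intersection(dosages.index)
    expr = expression[samples]
    cov = cov.loc[samples]

    records: list[EqtlResult] = []
    for var in variants:
        g = dosages.loc[samples, var]
        var_results = [
            fit_probe(expr.loc[probe], g, cov, probe_id=probe, variant_id=var)
            for probe in expr.index
        ]
        pvals = np.array([r.p for r in var_results])
        fit_ok = np.isfinite(pvals)
        if fit_ok.sum() >= 10:
            qv, _ = qvalues(pvals[fit_ok])
            j = 0
            for i, r in enumerate(var_results):
                if fit_ok[i]:
                    r.q = qv[j]
                    j += 1
        records.extend(var_results)

    res = pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in records],
            "variant_id": [r.variant_id for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "p": [r.p for r in records],
            "q": [r.q for r in records],
            "n_used": [r.n_used for r in records],
            "status": [r.status for r in records],
        }
    )

    summary: dict[str, dict] = {}
    for var in variants:
        sub = res.loc[res["variant_id"] == var]
        sig_p = sub.loc[sub["p"] <= alpha, "probe_id"]
        sig_q = sub.loc[sub["q"] <= q_thresh, "probe_id"]
        entry = {
            "n_probes_p": int(sig_p.size),
            "n_probes_q": int(sig_q.size),
        }
        if annotation is not None:
            genes_p = annotation.reindex(sig_p)
            genes_q = annotation.reindex(sig_q)
            entry["n_genes_p"] = int(genes_p.dropna().nunique())
            entry["n_genes_q"] = int(genes_q.dropna().nunique())
            n_unann = int(genes_p.isna().sum())
            if n_unann:
                logger.info(
                    "%d significant probes for %s lack gene annotation", n_unann, var
                )
            entry["n_probes_unannotated"] = n_unann
        summary[var] = entry
    return res, summary
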