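"""GEE logistic pharmacogenetic analysis of early medication cessation.

Several exposure episodes can come from the same individual, so early
cessation is modelled with a marginal logistic regression estimated by
generalized estimating equations (GEE), clustered by individual with an
exchangeable working correlation and robust (sandwich) standard errors.
Two models are fitted per (outcome group, variant):

    main:        cessation ~ dosage + gender
    interaction: cessation ~ dosage + gender + dosage:gender

Effects are reported as odds ratios with Wald 95% confidence intervals on
the log-odds scale.  Screens over individual drugs and over drug groups are
Bonferroni-corrected separately (alpha / number of tests in each screen).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["GeeFit", "BonferroniSpec", "gee_fit", "run_medication_screen"]

logger = logging.getLogger(__name__)


@dataclass
class GeeFit:
    """Odds ratios for one outcome group x variant."""

    outcome: str
    variant: str
    model: str  # "main" | "interaction"
    or_snp: float
    ci_snp: tuple[float, float]
    p_snp: float
    or_interaction: float | None = None
    ci_interaction: tuple[float, float] | None = None
    p_interaction: float | None = None
    n_individuals: int = 0
    n_instances: int = 0
    status: str = "ok"


@dataclass
class BonferroniSpec:
    """Per-screen multiple-testing threshold alpha / n_tests."""

    n_tests: int
    alpha: float = 0.05

    @property
    def threshold(self) -> float:
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")
        return self.alpha / self.n_tests


def _failed(outcome, variant, model, instances, reason) -> GeeFit:
    return GeeFit(
        outcome, variant, model,
        or_snp=float("nan"), ci_snp=(float("nan"), float("nan")), p_snp=float("nan"),
        n_individuals=instances["individual_id"].nunique(),
        n_instances=len(instances), status=reason,
    )


def gee_fit(
    instances: pd.DataFrame,
    variant: str,
    model: str = "interaction",
    outcome_label: str = "",
    cov_struct: str = "exchangeable",
    include_gender_main: bool = True,
) -> GeeFit:
    """Fit the GEE logistic model for one variant on one instance table.

    ``instances`` needs ``early_cessation``, ``gender``, ``individual_id``
    and a dosage column named ``variant``.  ``cov_struct`` selects the
    working correlation ("exchangeable" or "independence").  Separation or
    non-convergence yields a flagged fit rather than an exception.
    """
    import statsmodels.api as sm

    cols = ["early_cessation", "gender", "individual_id", variant]
    d = instances[cols].dropna()
    if d.empty or d["individual_id"].nunique() < 2:
        raise ValueError("need at least 2 clusters")
    y = d["early_cessation"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome is constant")

    g = d[variant].to_numpy(dtype=float)
    sex = d["gender"].to_numpy(dtype=float)
    cols_x = [np.ones_like(y), g]
    names = ["const", "dosage"]
    if include_gender_main or model == "interaction":
        cols_x.append(sex)
        names.append("gender")
    if model == "interaction":
        cols_x.append(g * sex)
        names.append("dosage:gender")
    X = np.column_stack(cols_x)

    structs = {
        "exchangeable": sm.cov_struct.Exchangeable,
        "independence": sm.cov_struct.Independence,
    }
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gee = sm.GEE(
                y, X, groups=d["individual_id"].to_numpy(),
                family=sm.families.Binomial(), cov_struct=structs[cov_struct](),
            )
            res = gee.fit()
        params = np.asarray(res.params)
        se = np.asarray(res.bse)  # robust sandwich SE by default
        if not np.all(np.isfinite(se)) or np.any(se <= 0):
            raise ValueError("non-finite robust standard errors")
    except Exception as exc:  # noqa: BLE001
        logger.warning("GEE fit failed for %s / %s: %s", outcome_label, variant, exc)
        return _failed(outcome_label, variant, model, d, f"failed: {exc}")

    def wald(i: int) -> tuple[float, tuple[float, float], float]:
        lo = params[i] - 1.96 * se[i]
        hi = params[i] + 1.96 * se[i]
        p = float(2 * norm.sf(abs(params[i] / se[i])))
        return float(np.exp(params[i])), (float(np.exp(lo)), float(np.exp(hi))), p

    i_dose = names.index("dosage")
    or_snp, ci_snp, p_snp = wald(i_dose)
    fit = GeeFit(
        outcome_label, variant, model, or_snp, ci_snp, p_snp,
        n_individuals=d["individual_id"].nunique(), n_instances=len(d),
    )
    if model == "interaction":
        i_int = names.index("dosage:gender")
        fit.or_interaction, fit.ci_interaction, fit.p_interaction = wald(i_int)
    return fit


def run_medication_screen(
    drug_instances: dict[str, pd.DataFrame],
    group_instances: dict[str, pd.DataFrame],
    variants: list[str],
    alpha: float = 0.05,
    cov_struct: str = "exchangeable",
) -> pd.DataFrame:
    """Screen every variant against each analyzable drug and each drug group.

    Both the main and interaction models are fitted.  Bonferroni thresholds
    are computed within each screen: alpha / n_drugs for single drugs and
    alpha / n_groups for groups; fits that fail are reported with their
    status, never dropped, and never abort the screen.
    """
    rows = []
    screens = [("drug", drug_instances), ("group", group_instances)]
    for screen_name, tables in screens:
        n_tests = len(tables)
        if n_tests == 0:
            continue
        thr = BonferroniSpec(n_tests=n_tests, alpha=alpha).threshold
        for label, inst in tables.items():
            for variant in variants:
                for model in ("main", "interaction"):
                    try:
                        fit = gee_fit(
                            inst, variant, model=model, outcome_label=label,
                            cov_struct=cov_struct,
                        )
                    except ValueError as exc:
                        fit = _failed(label, variant, model, inst, f"failed: {exc}")
                    p_flagged = fit.p_interaction if model == "interaction" else fit.p_snp
                    rows.append(
                        {
                            "screen": screen_name,
                            "outcome": label,
                            "variant": variant,
                            "model": model,
                            "or_snp": fit.or_snp,
                            "ci_snp_low": fit.ci_snp[0],
                            "ci_snp_high": fit.ci_snp[1],
                            "p_snp": fit.p_snp,
                            "or_interaction": fit.or_interaction,
                            "ci_int_low": fit.ci_interaction[0] if fit.ci_interaction else None,
                            "ci_int_high": fit.ci_interaction[1] if fit.ci_interaction else None,
                            "p_interaction": fit.p_interaction,
                            "n_individuals": fit.n_individuals,
                            "n_instances": fit.n_instances,
                            "bonferroni_threshold": thr,
                            "bonferroni_significant": bool(
                                p_flagged is not None
                                and np.isfinite(p_flagged)
                                and p_flagged <= thr
                            ),
                            "status": fit.status,
                        }
                    )
    return pd.DataFrame(rows)
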