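"""Synthetic family cohorts with known ground truth.

Every downstream stage of the pipeline — expression QC, the mixed-model
eQTL screen, LD estimation, replication tallies, target enrichment and the
prescription-register pharmacogenetic analysis — is testable against cohorts
generated here, where every effect size is known by construction.

The generator emulates a family-based study design:

* two-locus (or 2^L-haplotype) genotypes are dropped through nuclear
  pedigrees: founders draw haplotype pairs from specified haplotype
  frequencies (hence a specified D'/r^2 between the loci) and offspring
  inherit one haplotype from each parent, without recombination;
* expression is additive in allele dosage with gender/age/diagnosis
  covariate effects, a family-level random intercept and Gaussian noise,
  plus detection p-values under which a configurable fraction of probes
  fails the detectability filter;
* a microRNA target-prediction matrix in which "target" status (>= k of
  n programs) is enriched among the true eQTL genes at a configurable odds
  ratio;
* a purchase register over a multi-year window in which the probability of
  early cessation follows a logistic model in genotype, gender and their
  interaction, at configurable odds ratios per drug.

Dates are integer day offsets from the start of the observation window; a
month is 30 days.  The same seed always yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .exprqc import ExpressionMatrix

__all__ = [
    "CovariateEffects",
    "DrugSpec",
    "CohortSpec",
    "GenotypeTable",
    "SyntheticExpression",
    "SyntheticRegister",
    "generate_genotypes",
    "generate_covariates",
    "generate_expression",
    "generate_target_matrix",
    "generate_purchases",
    "generate_cohort",
    "default_drugs",
]

DAYS_PER_YEAR = 365
# margin at the end of the window so continuing-use episodes are never censored
_WINDOW_MARGIN = 600
_MAX_REFILLS = 12


@dataclass(frozen=True)
class CovariateEffects:
    """Fixed-effect sizes of the covariates on log2 expression."""

    gender: float = 0.10
    age: float = 0.002  # per year
    diagnosis: float = 0.10


@dataclass(frozen=True)
class DrugSpec:
    """One simulated drug: ATC code, group tags and cessation-model effects.

    ``base_cessation_prob`` is the early-cessation probability for a
    genotype-0 male; ``genotype_or``, ``gender_or`` and ``interaction_or``
    multiply the odds per dosage unit, for females, and per dosage unit in
    females, respectively.  ``use_prob`` is the chance an affected
    individual uses the drug during the window.
    """

    atc_code: str
    is_ssri: bool
    cyp2c19: bool
    base_cessation_prob: float = 0.35
    genotype_or: float = 1.0
    gender_or: float = 1.0
    interaction_or: float = 1.0
    use_prob: float = 0.12


def default_drugs() -> tuple[DrugSpec, ...]:
    """Default drug panel: 7 CYP2C19-metabolized drugs of which 4 are SSRIs,
    2 SSRIs not metabolized by CYP2C19, and 2 drugs in neither group.

    Default effects mirror the study conditions the generator emulates: a
    protective genotype-by-gender interaction (OR 0.30) for SSRIs
    metabolized by CYP2C19, a risk interaction (OR 4.93) for non-SSRI
    CYP2C19 drugs, and a genotype main effect (OR 4.13) for one antipsychotic
    outside both groups.
    """
    return (
        DrugSpec("N06AB04", True, True, use_prob=0.10, interaction_or=0.30),
        DrugSpec("N06AB10", True, True, use_prob=0.10, interaction_or=0.30),
        DrugSpec("N06AB06", True, True, use_prob=0.10, interaction_or=0.30),
        DrugSpec("N06AB03", True, True, use_prob=0.10, interaction_or=0.30),
        DrugSpec("N06AB05", True, False, use_prob=0.08),
        DrugSpec("N06AB08", True, False, use_prob=0.08),
        DrugSpec("N05BA01", False, True, use_prob=0.24, interaction_or=4.93),
        DrugSpec("N06AA09", False, True, use_prob=0.24, interaction_or=4.93),
        DrugSpec("N05AA02", False, False, use_prob=0.12, genotype_or=4.13),
        DrugSpec("N05AH03", False, False, use_prob=0.12),
    )


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; the seed fully determines output."""

    n_families: int = 150
    family_size_range: tuple[int, int] = (2, 6)
    # two-locus haplotype frequencies (AB, Ab, aB, ab); allele frequency 0.35
    # at both loci, r^2 = 0.88 between them (minor-hom frequency ~12% so the
    # default variants pass the 10% expression-arm inclusion cut-off)
    haplotype_freqs: tuple[float, ...] = (
        0.335913917071966,
        0.014086082928033955,
        0.014086082928033955,
        0.6359139170719661,
    )
    n_probes: int = 1000
    n_true_eqtl: int = 100
    eqtl_effect: float = 0.52
    eqtl_variant: str = "snp1"
    family_sd: float = 0.25
    residual_sd: float = 0.53
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    n_programs: int = 12
    target_k: int = 6
    target_base_rate: float = 2588 / 16027
    target_enrichment_or: float = 3.0
    drugs: tuple[DrugSpec, ...] = field(default_factory=default_drugs)
    pharmaco_variant: str = "snp1"
    years: int = 10
    affected_fraction: float = 23 / 64
    frac_undetected: float = 0.15
    # optional: pin which probes carry the effect (shared truth across cohorts)
    true_probe_indices: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.haplotype_freqs, dtype=float)
        n_loci = int(np.log2(f.size))
        if 2**n_loci != f.size:
            raise ValueError("haplotype_freqs length must be a power of 2")
        if (f < 0).any() or (f > 1).any() or abs(f.sum() - 1) > 1e-12:
            raise ValueError("haplotype_freqs must be probabilities summing to 1")
        if self.n_true_eqtl > self.n_probes:
            raise ValueError("n_true_eqtl cannot exceed n_probes")
        lo, hi = self.family_size_range
        if lo < 2 or hi < lo:
            raise ValueError("family sizes must satisfy 2 <= min <= max")
        for p in (self.affected_fraction, self.frac_undetected, self.target_base_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.target_enrichment_or < 0:
            raise ValueError("target_enrichment_or must be non-negative")

    @property
    def n_loci(self) -> int:
        return int(np.log2(len(self.haplotype_freqs)))

    @property
    def window_days(self) -> int:
        return self.years * DAYS_PER_YEAR


@dataclass
class GenotypeTable:
    """Allele-dosage matrix with pedigree structure.

    ``dosages`` is individuals x variants (counts of allele 1, NaN for
    missing); ``meta`` is indexed by individual with ``family_id``,
    ``father_id``, ``mother_id`` and ``is_founder``; ``haplotypes`` stores
    the generating (phased) haplotype indices per individual, the ground
    truth for LD tests.
    """

    dosages: pd.DataFrame
    meta: pd.DataFrame
    haplotypes: pd.DataFrame | None = None

    @property
    def individuals(self) -> pd.Index:
        return self.dosages.index

    @property
    def variants(self) -> pd.Index:
        return self.dosages.columns


@dataclass
class SyntheticExpression:
    """Raw expression matrix plus the ground truth that generated it."""

    matrix: ExpressionMatrix  # raw intensities + detection p-values
    log2: pd.DataFrame  # underlying log2-scale values (pre-QC truth)
    annotation: pd.Series  # probe -> gene symbol
    true_probes: list[str]
    undetected_probes: list[str]


@dataclass
class SyntheticRegister:
    """Purchase records plus the per-episode cessation ground truth."""

    register: pd.DataFrame  # individual_id, atc_code, purchase_day, ddd_amount
    truth: pd.DataFrame  # individual_id, atc_code, start_day, early (bool)
    drug_map: pd.DataFrame  # atc_code -> is_ssri, cyp2c19


def _hap_dosages(haps: np.ndarray, n_loci: int) -> np.ndarray:
    """Dosage matrix (n x n_loci) from an n x 2 array of haplotype indices."""
    out = np.zeros((haps.shape[0], n_loci), dtype=float)
    for locus in range(n_loci):
        shift = n_loci - 1 - locus
        out[:, locus] = ((haps[:, 0] >> shift) & 1) + ((haps[:, 1] >> shift) & 1)
    return out


def generate_genotypes(spec: CohortSpec, rng: np.random.Generator | None = None) -> GenotypeTable:
    """Drop haplotypes through nuclear families.

    Each family has two founders whose haplotype pairs are multinomial draws
    from ``spec.haplotype_freqs``; every further member is an offspring
    inheriting one (unrecombined) haplotype from each founder.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    freqs = np.asarray(spec.haplotype_freqs, dtype=float)
    n_loci = spec.n_loci
    n_haps = freqs.size

    ids, fam_ids, fathers, mothers, founder_flags = [], [], [], [], []
    hap_rows = []
    for fam in range(spec.n_families):
        size = int(rng.integers(spec.family_size_range[0], spec.family_size_range[1] + 1))
        fam_name = f"F{fam:04d}"
        father, mother = f"{fam_name}_01", f"{fam_name}_02"
        f_haps = rng.choice(n_haps, size=2, p=freqs)
        m_haps = rng.choice(n_haps, size=2, p=freqs)
        for ind, haps in ((father, f_haps), (mother, m_haps)):
            ids.append(ind)
            fam_ids.append(fam_name)
            fathers.append(None)
            mothers.append(None)
            founder_flags.append(True)
            hap_rows.append(haps)
        for k in range(size - 2):
            child = f"{fam_name}_{k + 3:02d}"
            haps = np.array(
                [f_haps[rng.integers(2)], m_haps[rng.integers(2)]]
            )
            ids.append(child)
            fam_ids.append(fam_name)
            fathers.append(father)
            mothers.append(mother)
            founder_flags.append(False)
            hap_rows.append(haps)

    haps = np.asarray(hap_rows)
    dosages = pd.DataFrame(
        _hap_dosages(haps, n_loci),
        index=pd.Index(ids, name="individual_id"),
        columns=[f"snp{i + 1}" for i in range(n_loci)],
    )
    meta = pd.DataFrame(
        {
            "family_id": fam_ids,
            "father_id": fathers,
            "mother_id": mothers,
            "is_founder": founder_flags,
        },
        index=dosages.index,
    )
    hap_df = pd.DataFrame(haps, index=dosages.index, columns=["hap1", "hap2"])
    return GenotypeTable(dosages=dosages, meta=meta, haplotypes=hap_df)


def generate_covariates(
    gt: GenotypeTable, spec: CohortSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Gender, age and diagnostic status per individual.

    Affection status is Bernoulli(``affected_fraction``) per individual,
    reflecting the affected-to-total ratio of an ascertained family cohort.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    n = len(gt.individuals)
    cov = pd.DataFrame(
        {
            "gender": rng.integers(0, 2, size=n),
            "age": rng.integers(18, 71, size=n),
            "diagnosis": (rng.random(n) < spec.affected_fraction).astype(int),
            "family_id": gt.meta["family_id"].to_numpy(),
            "cohort_role": "discovery",
        },
        index=gt.individuals,
    )
    return cov


def generate_expression(
    gt: GenotypeTable,
    cov: pd.DataFrame,
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> SyntheticExpression:
    """Expression with additive genotype effects on the true eQTL probes.

    log2 expression = probe baseline + beta * dosage (true probes only)
    + covariate effects + family random intercept + Gaussian noise.  Raw
    intensities are 2**log2.  Detection p-values are Beta(1, 500) for
    expressed probes (essentially always detected) and Uniform(0, 1) for a
    ``frac_undetected`` fraction of null probes, which therefore fail the
    >90% detectability filter.
    """
    rng = np.random.default_rng(spec.seed + 2) if rng is None else rng
    samples = gt.individuals
    n_samp = len(samples)
    probes = [f"probe{i:05d}" for i in range(spec.n_probes)]

    # probes map many-to-one onto genes: every 5th probe repeats a gene symbol
    gene_ids, gene_idx = [], -1
    for i in range(spec.n_probes):
        if i % 5 == 4:
            gene_ids.append(f"GENE{gene_idx:05d}")
        else:
            gene_idx += 1
            gene_ids.append(f"GENE{gene_idx:05d}")
    annotation = pd.Series(gene_ids, index=pd.Index(probes, name="probe_id"), name="gene")

    if spec.true_probe_indices is not None:
        true_probes = sorted(spec.true_probe_indices)
    else:
        true_probes = sorted(
            rng.choice(spec.n_probes, size=spec.n_true_eqtl, replace=False)
        )
    true_set = set(true_probes)
    null_probes = [i for i in range(spec.n_probes) if i not in true_set]
    n_undet = int(round(spec.frac_undetected * spec.n_probes))
    n_undet = min(n_undet, len(null_probes))
    undetected = set(rng.choice(null_probes, size=n_undet, replace=False))

    g = gt.dosages[spec.eqtl_variant].to_numpy()
    eff = spec.covariate_effects
    cov_term = (
        eff.gender * cov["gender"].to_numpy()
        + eff.age * cov["age"].to_numpy()
        + eff.diagnosis * cov["diagnosis"].to_numpy()
    )
    fam_codes, fam_uniques = pd.factorize(cov["family_id"])
    n_fam = len(fam_uniques)

    baseline = rng.normal(8.0, 1.0, size=spec.n_probes)
    fam_effects = rng.normal(0.0, spec.family_sd, size=(spec.n_probes, n_fam))
    noise = rng.normal(0.0, spec.residual_sd, size=(spec.n_probes, n_samp))

    y = baseline[:, None] + cov_term[None, :] + fam_effects[:, fam_codes] + noise
    beta = np.zeros(spec.n_probes)
    beta[list(true_probes)] = spec.eqtl_effect
    y += beta[:, None] * g[None, :]

    detection = np.empty((spec.n_probes, n_samp))
    expressed_p = rng.beta(1.0, 500.0, size=(spec.n_probes, n_samp))
    uniform_p = rng.random((spec.n_probes, n_samp))
    undet_mask = np.zeros(spec.n_probes, dtype=bool)
    undet_mask[list(undetected)] = True
    detection[~undet_mask] = expressed_p[~undet_mask]
    detection[undet_mask] = uniform_p[undet_mask]

    log2_df = pd.DataFrame(y, index=probes, columns=samples)
    matrix = ExpressionMatrix(
        intensities=pd.DataFrame(2.0**y, index=probes, columns=samples),
        detection_p=pd.DataFrame(detection, index=probes, columns=samples),
        normalized=False,
        annotation=annotation,
    )
    return SyntheticExpression(
        matrix=matrix,
        log2=log2_df,
        annotation=annotation,
        true_probes=[probes[i] for i in true_probes],
        undetected_probes=[probes[i] for i in sorted(undetected)],
    )


def generate_target_matrix(
    gene_ids: list[str],
    true_eqtl_genes: set[str],
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Program-prediction matrix with configurable target enrichment.

    "Target" status (>= ``target_k`` of ``n_programs`` programs predicting)
    is Bernoulli with base rate ``target_base_rate``; among true eQTL genes
    the odds are multiplied by ``target_enrichment_or``.  Given the status,
    the number of predicting programs is drawn above or below the k
    threshold and assigned to a random subset of programs.
    """
    rng = np.random.default_rng(spec.seed + 3) if rng is None else rng
    unknown = set(true_eqtl_genes) - set(gene_ids)
    if unknown:
        raise ValueError("true eQTL genes must be a subset of gene_ids")
    p0 = spec.target_base_rate
    orr = spec.target_enrichment_or
    if np.isinf(orr):
        p1 = 1.0
    else:
        odds1 = orr * p0 / (1 - p0) if p0 < 1 else np.inf
        p1 = odds1 / (1 + odds1) if np.isfinite(odds1) else 1.0
    if not 0 <= p1 <= 1:
        raise ValueError("enrichment odds ratio unattainable at these marginals")

    k, n_prog = spec.target_k, spec.n_programs
    n_genes = len(gene_ids)
    is_true = np.fromiter((g in true_eqtl_genes for g in gene_ids), bool, n_genes)
    p_target = np.where(is_true, p1, p0)
    is_target = rng.random(n_genes) < p_target
    counts = np.where(
        is_target,
        k + rng.binomial(n_prog - k, 0.4, size=n_genes),
        rng.binomial(k - 1, 0.45, size=n_genes),
    )
    # a random subset of `counts[i]` programs predicts gene i
    ranks = np.argsort(rng.random((n_genes, n_prog)), axis=1).argsort(axis=1)
    mat = (ranks < counts[:, None]).astype(int)
    return pd.DataFrame(
        mat,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"prog{j + 1:02d}" for j in range(n_prog)],
    )


def generate_purchases(
    gt: GenotypeTable,
    cov: pd.DataFrame,
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> SyntheticRegister:
    """Purchase histories whose early-cessation probability is logistic in
    (genotype, gender, genotype x gender).

    Early-cessation users make a single purchase whose stretched supply is
    at most ~77 days; continuing users refill 30-DDD purchases with gaps of
    at most 12 days until at least four refills, well past the 90-day
    cut-off.  Episode starts leave a margin before the window end so
    continuing episodes are never right-censored.
    """
    if not spec.drugs:
        raise ValueError("drugs list must be nonempty")
    rng = np.random.default_rng(spec.seed + 4) if rng is None else rng
    affected = cov.index[cov["diagnosis"] == 1]
    g_all = gt.dosages[spec.pharmaco_variant]

    rows, truth_rows = [], []
    latest_start = spec.window_days - _WINDOW_MARGIN
    for ind in affected:
        g = float(g_all.loc[ind])
        sex = float(cov.loc[ind, "gender"])
        for drug in spec.drugs:
            if rng.random() >= drug.use_prob:
                continue
            eta = (
                logit(drug.base_cessation_prob)
                + np.log(drug.genotype_or) * g
                + np.log(drug.gender_or) * sex
                + np.log(drug.interaction_or) * g * sex
            )
            early = rng.random() < expit(eta)
            start = int(rng.integers(0, latest_start))
            if early:
                ddd = int(rng.integers(10, 71))  # stretched supply 11-78 days <= 90
                rows.append((ind, drug.atc_code, start, ddd))
            else:
                n_fills = int(min(4 + rng.poisson(4), _MAX_REFILLS))
                day = start
                for _ in range(n_fills):
                    rows.append((ind, drug.atc_code, int(round(day)), 30))
                    day += 33 + rng.integers(0, 13)  # refill within the 15-day gap
            truth_rows.append((ind, drug.atc_code, start, bool(early)))

    register = pd.DataFrame(
        rows, columns=["individual_id", "atc_code", "purchase_day", "ddd_amount"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["individual_id", "atc_code", "start_day", "early"]
    )
    drug_map = pd.DataFrame(
        {
            "is_ssri": [d.is_ssri for d in spec.drugs],
            "cyp2c19": [d.cyp2c19 for d in spec.drugs],
        },
        index=pd.Index([d.atc_code for d in spec.drugs], name="atc_code"),
    )
    return SyntheticRegister(register=register, truth=truth, drug_map=drug_map)


def generate_cohort(spec: CohortSpec) -> dict:
    """Generate every cohort component from one spec (seed-deterministic)."""
    gt = generate_genotypes(spec)
    cov = generate_covariates(gt, spec)
    expr = generate_expression(gt, cov, spec)
    true_genes = set(expr.annotation.loc[expr.true_probes])
    targets = generate_target_matrix(
        sorted(expr.annotation.unique()), true_genes, spec
    )
    purchases = generate_purchases(gt, cov, spec)
    return {
        "spec": spec,
        "genotypes": gt,
        "covariates": cov,
        "expression": expr,
        "targets": targets,
        "purchases": purchases,
    }
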