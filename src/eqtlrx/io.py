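"""File formats, pipeline configuration and the end-to-end orchestrator.

On disk the pipeline speaks plain text: VCF for genotypes (unphased GT),
TSV for expression/detection matrices, covariates, target-prediction
matrices and drug-group maps, CSV for purchase registers (ISO-8601 dates),
and JSON for summaries.  Internally dates are integer day offsets from a
configurable epoch and episode intervals are half-open.

``run_all`` executes the full chain — simulate (optional), expression QC,
the eQTL screen, LD, replication tallies, target enrichment, exposure
episodes and the GEE medication screen — and writes a manifest (inputs,
parameters, versions, seed) sufficient to reproduce every output
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, eqtl, ld, medication, pharmacogee, replication, synthdata
from .exprqc import ExpressionMatrix, detection_filter, normalize

__all__ = [
    "PipelineConfig",
    "read_config",
    "run_all",
    "write_vcf",
    "read_vcf_dosages",
    "write_expression",
    "read_expression",
    "write_covariates",
    "read_covariates",
    "write_register",
    "read_register",
    "write_drug_map",
    "read_drug_map",
    "write_target_matrix",
    "read_target_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_EPOCH = "1996-01-01"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_vcf(gt: synthdata.GenotypeTable, path: str | Path) -> None:
    """Write dosages as a minimal VCF with unphased GT calls."""
    path = Path(path)
    samples = list(gt.individuals)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for i, var in enumerate(gt.variants):
            calls = []
            for d in gt.dosages[var]:
                if np.isnan(d):
                    calls.append("./.")
                else:
                    calls.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
            fh.write(
                f"1\t{1000 * (i + 1)}\t{var}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf_dosages(path: str | Path) -> pd.DataFrame:
    """Read a VCF into an individuals x variants dosage matrix (ALT counts).

    Missing calls (./.) become NaN and are pairwise-dropped downstream.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    data = {}
    for variant in vcf:
        dos = []
        for call in variant.genotypes:
            a, b = call[0], call[1]
            dos.append(float(a + b) if a >= 0 and b >= 0 else np.nan)
        data[variant.ID] = dos
    return pd.DataFrame(data, index=pd.Index(samples, name="individual_id"))


def write_expression(m: ExpressionMatrix, intensities: str | Path, detection: str | Path | None = None) -> None:
    m.intensities.to_csv(intensities, sep="\t")
    if detection is not None and m.detection_p is not None:
        m.detection_p.to_csv(detection, sep="\t")


def read_expression(
    intensities: str | Path,
    detection: str | Path | None = None,
    annotation: str | Path | None = None,
    normalized: bool = False,
) -> ExpressionMatrix:
    inten = pd.read_csv(intensities, sep="\t", index_col=0)
    det = pd.read_csv(detection, sep="\t", index_col=0) if detection else None
    ann = None
    if annotation:
        ann_df = pd.read_csv(annotation, sep="\t", index_col=0)
        ann = ann_df.iloc[:, 0]
    return ExpressionMatrix(inten, det, normalized=normalized, annotation=ann)


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, sep="\t", index_label="individual_id")


def read_covariates(path: str | Path) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t", index_col="individual_id")
    if cov["family_id"].isna().any():
        bad = cov.index[cov["family_id"].isna()][0]
        raise ValueError(f"missing family_id for individual {bad!r}")
    return cov


def write_register(
    register: pd.DataFrame, path: str | Path, epoch: str = DEFAULT_EPOCH
) -> None:
    """Write purchases as CSV with ISO-8601 dates (day offsets -> calendar)."""
    out = register.copy()
    dates = pd.to_datetime(epoch) + pd.to_timedelta(out["purchase_day"], unit="D")
    out["purchase_date"] = dates.dt.strftime("%Y-%m-%d")
    out[["individual_id", "atc_code", "purchase_date", "ddd_amount"]].to_csv(
        path, index=False
    )


def read_register(path: str | Path, epoch: str = DEFAULT_EPOCH) -> pd.DataFrame:
    """Read a purchase CSV; strict validation with line-numbered errors."""
    df = pd.read_csv(path)
    required = {"individual_id", "atc_code", "purchase_date", "ddd_amount"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    ddd = pd.to_numeric(df["ddd_amount"], errors="coerce")
    bad = ddd.isna() | (ddd <= 0)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
        raise ValueError(f"{path}: line {line}: non-positive or malformed ddd_amount")
    try:
        dates = pd.to_datetime(df["purchase_date"], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: malformed purchase_date: {exc}") from exc
    df["purchase_day"] = (dates - pd.to_datetime(epoch)).dt.days
    df["ddd_amount"] = ddd
    return df[["individual_id", "atc_code", "purchase_day", "ddd_amount"]]


def write_drug_map(drug_map: pd.DataFrame, path: str | Path) -> None:
    drug_map.astype(int).to_csv(path, sep="\t", index_label="atc_code")


def read_drug_map(path: str | Path) -> pd.DataFrame:
    dm = pd.read_csv(path, sep="\t", index_col="atc_code")
    return dm.astype(bool)


def write_target_matrix(targets: pd.DataFrame, path: str | Path) -> None:
    targets.astype(int).to_csv(path, sep="\t", index_label="gene_id")


def read_target_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the canonical protocol values."""

    outdir: str = "results"
    seed: int = 0
    simulate: bool = True
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    paths: dict = field(default_factory=dict)  # real-data inputs when simulate=False
    detection_p: float = 0.01
    detection_frac: float = 0.90
    alpha: float = 0.05
    q_thresh: float = 0.05
    target_k: int = 6
    stretch: float = 1.1
    gap_days: int = 15
    cutoff_days: float = 90
    min_instances: int = 15
    min_minor_hom_freq_expr: float = 0.10
    min_minor_hom_freq_med: float = 0.05
    epoch: str = DEFAULT_EPOCH
    twin_n_families: int = 40


def read_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

def _cohort_spec(config: PipelineConfig) -> synthdata.CohortSpec:
    overrides = dict(config.cohort)
    if "drugs" in overrides:
        overrides["drugs"] = tuple(
            synthdata.DrugSpec(**d) for d in overrides["drugs"]
        )
    if "family_size_range" in overrides:
        overrides["family_size_range"] = tuple(overrides["family_size_range"])
    if "haplotype_freqs" in overrides:
        overrides["haplotype_freqs"] = tuple(overrides["haplotype_freqs"])
    if "covariate_effects" in overrides:
        overrides["covariate_effects"] = synthdata.CovariateEffects(
            **overrides["covariate_effects"]
        )
    overrides.setdefault("seed", config.seed)
    return synthdata.CohortSpec(**overrides)


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all result files plus a manifest.

    With ``simulate=True`` a synthetic cohort (including an independent
    "twin" replication cohort sharing the true eQTL probes) is generated and
    written under ``outdir/inputs`` before being analyzed exactly as real
    inputs would be.  Any stage failure raises with the stage name.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if config.simulate:
            stage = "simulate"
            spec = _cohort_spec(config)
            cohort = synthdata.generate_cohort(spec)
            gt, cov = cohort["genotypes"], cohort["covariates"]
            sexpr = cohort["expression"]
            targets_df = cohort["targets"]
            reg = cohort["purchases"]
            inputs = out / "inputs"
            inputs.mkdir(exist_ok=True)
            write_vcf(gt, inputs / "genotypes.vcf")
            write_covariates(cov, inputs / "covariates.tsv")
            write_expression(
                sexpr.matrix, inputs / "expression.tsv", inputs / "detection_p.tsv"
            )
            sexpr.annotation.to_frame().to_csv(inputs / "annotation.tsv", sep="\t")
            write_target_matrix(targets_df, inputs / "targets.tsv")
            write_register(reg.register, inputs / "purchases.csv", epoch=config.epoch)
            write_drug_map(reg.drug_map, inputs / "drug_map.tsv")
            raw = sexpr.matrix
            dosages = gt.dosages
            annotation = sexpr.annotation
            register = reg.register
            drug_map = reg.drug_map

            # independent replication cohort sharing the true probe set
            probes = list(raw.probe_ids)
            true_idx = tuple(probes.index(p) for p in sexpr.true_probes)
            twin_spec = replace(
                spec,
                n_families=config.twin_n_families,
                seed=spec.seed + 104729,
                true_probe_indices=true_idx,
            )
            twin_gt = synthdata.generate_genotypes(twin_spec)
            twin_cov = synthdata.generate_covariates(twin_gt, twin_spec)
            twin_cov["cohort_role"] = "twin"
            twin_expr = synthdata.generate_expression(twin_gt, twin_cov, twin_spec)
        else:
            stage = "load"
            p = config.paths
            raw = read_expression(
                p["expression"], p.get("detection_p"), p.get("annotation")
            )
            dosages = (
                read_vcf_dosages(p["genotypes_vcf"])
                if "genotypes_vcf" in p
                else pd.read_csv(p["genotypes_tsv"], sep="\t", index_col=0)
            )
            cov = read_covariates(p["covariates"])
            annotation = raw.annotation
            targets_df = read_target_matrix(p["targets"]) if "targets" in p else None
            register = read_register(p["purchases"], epoch=config.epoch) if "purchases" in p else None
            drug_map = read_drug_map(p["drug_map"]) if "drug_map" in p else None
            twin_expr = twin_gt = twin_cov = None

        stage = "qc"
        filtered = detection_filter(raw, config.detection_p, config.detection_frac)
        normed = normalize(filtered)
        write_expression(normed, out / "expression_qc.tsv")

        stage = "eqtl"
        variants = eqtl.select_variants(
            dosages, config.min_minor_hom_freq_expr, samples=normed.sample_ids
        )
        results, summary = eqtl.run_screen(
            normed.intensities, dosages, cov, variants,
            annotation=annotation, alpha=config.alpha, q_thresh=config.q_thresh,
        )
        results.to_csv(out / "eqtl_results.tsv", sep="\t", index=False)
        with open(out / "eqtl_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

        stage = "ld"
        ld_rows = []
        for i, v1 in enumerate(dosages.columns):
            for v2 in dosages.columns[i + 1:]:
                stats = ld.ld_between(dosages[v1], dosages[v2])
                ld_rows.append(
                    {"variant1": v1, "variant2": v2, "D": stats.D,
                     "D_prime": stats.D_prime, "r2": stats.r2, "n": stats.n}
                )
        ld_df = pd.DataFrame(ld_rows)
        ld_df.to_csv(out / "ld.tsv", sep="\t", index=False)

        stage = "replicate"
        rep_summary = None
        if len(variants) >= 1:
            primary = variants[0]
            disc = results.loc[results["variant_id"] == primary]
            ld_partner = (
                results.loc[results["variant_id"] == variants[1]]
                if len(variants) > 1 else None
            )
            twin_results = None
            if config.simulate and twin_expr is not None:
                twin_norm = normalize(
                    detection_filter(twin_expr.matrix, config.detection_p, config.detection_frac)
                )
                twin_results, _ = eqtl.run_screen(
                    twin_norm.intensities, twin_gt.dosages, twin_cov, [primary],
                    annotation=twin_expr.annotation, alpha=config.alpha,
                )
            tally, rep_summary = replication.tally_support(
                disc, ld_partner=ld_partner, twin=twin_results, external=None,
                annotation=annotation, alpha=config.alpha,
            )
            tally.to_csv(out / "replication_tally.tsv", sep="\t", index=False)
            with open(out / "replication_summary.json", "w") as fh:
                json.dump(rep_summary, fh, indent=2, sort_keys=True)

        stage = "enrich"
        enr = None
        if targets_df is not None and annotation is not None and len(variants) >= 1:
            target_set = enrichment.filter_targets(targets_df, config.target_k)
            primary = variants[0]
            sub = results.loc[results["variant_id"] == primary]
            tested_genes = set(annotation.reindex(sub["probe_id"]).dropna())
            sig_genes = set(
                annotation.reindex(sub.loc[sub["q"] <= config.q_thresh, "probe_id"]).dropna()
            )
            if sig_genes:
                res = enrichment.enrich(
                    sig_genes, target_set & tested_genes, tested_genes
                )
                enr = {
                    "p_value": res.p_value,
                    "fold_enrichment": res.fold_enrichment,
                    "table": res.table,
                }
                with open(out / "enrichment.json", "w") as fh:
                    json.dump(enr, fh, indent=2, sort_keys=True)

        stage = "episodes"
        gee_df = None
        if register is not None:
            window_end = None
            if config.simulate:
                window_end = _cohort_spec(config).window_days
            episodes = medication.build_episodes(
                register, stretch=config.stretch, gap_days=config.gap_days,
                window_end=window_end,
            )
            episodes.to_csv(out / "episodes.tsv", sep="\t", index=False)
            med_variants = eqtl.select_variants(dosages, config.min_minor_hom_freq_med)
            instances = medication.derive_cessation(
                episodes, cutoff_days=config.cutoff_days,
                covariates=cov, genotypes=dosages, drug_map=drug_map,
            )
            instances.to_csv(out / "instances.tsv", sep="\t", index=False)

            stage = "pharmaco"
            single_drugs = medication.filter_drugs(instances, config.min_instances)
            drug_tables = {
                d: instances.loc[instances["atc_code"] == d] for d in single_drugs
            }
            groups = (
                medication.group_instances(instances, drug_map)
                if drug_map is not None else {}
            )
            gee_df = pharmacogee.run_medication_screen(
                drug_tables, groups, med_variants, alpha=config.alpha
            )
            gee_df.to_csv(out / "medication_screen.tsv", sep="\t", index=False)

        stage = "manifest"
        import scipy
        import statsmodels

        manifest = {
            "seed": config.seed,
            "parameters": dataclasses.asdict(config),
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
                "statsmodels": statsmodels.__version__,
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return {
        "eqtl_results": results,
        "eqtl_summary": summary,
        "ld": ld_df,
        "replication_summary": rep_summary,
        "enrichment": enr,
        "medication_screen": gee_df,
        "outdir": str(out),
    }
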