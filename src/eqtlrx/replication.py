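"""Multi-source replication tallies for discovery eQTL hits.

Probes nominally significant in the discovery screen (p <= 0.05, before any
FDR correction) are checked against up to three independent lines of
evidence:

* ``high_ld_snp`` — association with a second variant in high LD with the
  discovery variant, within the same cohort (internal replication);
* ``twin_cohort`` — association in an independent replication cohort;
* ``external_db`` — a gene-level result table from an external eQTL
  database (e.g. a whole-blood lookup), matched by gene symbol.

Each probe receives the subset of sources in which it replicates and the
summary counts probes (and distinct genes) supported by >= 1, >= 2 and all
3 sources.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["tally_support", "overlap_with_prior"]

logger = logging.getLogger(__name__)

SOURCES = ("high_ld_snp", "twin_cohort", "external_db")


def _sig_probes(table: pd.DataFrame | None, alpha: float) -> set:
    if table is None or table.empty:
        return set()
    return set(table.loc[table["p"] <= alpha, "probe_id"])


def tally_support(
    discovery: pd.DataFrame,
    ld_partner: pd.DataFrame | None = None,
    twin: pd.DataFrame | None = None,
    external: pd.DataFrame | None = None,
    annotation: pd.Series | None = None,
    alpha: float = 0.05,
    same_direction: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Tally replication sources per discovery-significant probe.

    ``discovery``, ``ld_partner`` and ``twin`` are probe-level result tables
    with ``probe_id`` and ``p`` (and ``beta`` when ``same_direction`` is
    requested); ``external`` is gene-keyed with ``gene`` and ``p``.
    ``annotation`` maps probe -> gene symbol; probes without an official
    gene name are excluded from external matching.  A probe absent from a
    source's table counts as non-supporting and is recorded in the coverage
    report.
    """
    sig = discovery.loc[discovery["p"] <= alpha].copy()
    if annotation is not None:
        sig["gene"] = annotation.reindex(sig["probe_id"]).to_numpy()
    elif "gene" not in sig.columns:
        sig["gene"] = None

    ld_sig = _sig_probes(ld_partner, alpha)
    twin_sig = _sig_probes(twin, alpha)
    ext_sig = set()
    if external is not None and not external.empty:
        ext_sig = set(external.loc[external["p"] <= alpha, "gene"])

    if same_direction:
        disc_sign = dict(zip(discovery["probe_id"], np.sign(discovery["beta"])))

        def directional(table, members):
            if table is None:
                return members
            signs = dict(zip(table["probe_id"], np.sign(table["beta"])))
            return {p for p in members if signs.get(p) == disc_sign.get(p)}

        ld_sig = directional(ld_partner, ld_sig)
        twin_sig = directional(twin, twin_sig)

    coverage = {
        "high_ld_snp": 0,
        "twin_cohort": 0,
        "external_db": 0,
    }
    ld_probes = set(ld_partner["probe_id"]) if ld_partner is not None else set()
    twin_probes = set(twin["probe_id"]) if twin is not None else set()
    ext_genes = set(external["gene"]) if external is not None else set()

    rows = []
    for probe, gene in zip(sig["probe_id"], sig["gene"]):
        sources = []
        if probe in ld_sig:
            sources.append("high_ld_snp")
        if probe in twin_sig:
            sources.append("twin_cohort")
        gene_known = gene is not None and not (isinstance(gene, float) and np.isnan(gene))
        if gene_known and gene in ext_sig:
            sources.append("external_db")
        coverage["high_ld_snp"] += probe in ld_probes
        coverage["twin_cohort"] += probe in twin_probes
        coverage["external_db"] += gene_known and gene in ext_genes
        rows.append((probe, gene, ",".join(sources), len(sources)))

    tally = pd.DataFrame(rows, columns=["probe_id", "gene", "sources", "n_sources"])

    def counts(min_n: int, exact: bool = False) -> tuple[int, int]:
        mask = tally["n_sources"] == min_n if exact else tally["n_sources"] >= min_n
        sub = tally.loc[mask]
        return int(len(sub)), int(sub["gene"].dropna().nunique())

    p1, g1 = counts(1)
    p2, g2 = counts(2)
    p3, g3 = counts(3, exact=True)
    summary = {
        "n_discovery_probes": int(len(tally)),
        "probes_ge1": p1, "genes_ge1": g1,
        "probes_ge2": p2, "genes_ge2": g2,
        "probes_eq3": p3, "genes_eq3": g3,
        "coverage": coverage,
    }
    return tally, summary


def overlap_with_prior(current_genes: set, prior_genes: set) -> tuple[int, int]:
    """Overlap of a replicated gene set with a prior study's gene list.

    Returns (count, percentage of the prior list, rounded to the nearest
    integer percent).
    """
    if not prior_genes:
        raise ValueError("empty prior gene set")
    overlap = len(set(current_genes) & set(prior_genes))
    pct = int(round(100 * overlap / len(prior_genes)))
    return overlap, pct
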