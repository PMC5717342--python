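"""MicroRNA target-set enrichment.

A target-prediction matrix records, per gene, which of a panel of prediction
programs (12 by default, mirroring aggregator databases such as miRWalk)
call the gene a target of a microRNA of interest.  Genes predicted by at
least ``k`` of the programs form the target set, and over-representation of
targets among the genes flagged by an expression screen is tested with the
one-sided hypergeometric tail, conditioning on the set of genes actually
tested (the universe).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

__all__ = ["EnrichmentResult", "filter_targets", "enrich"]


@dataclass
class EnrichmentResult:
    p_value: float
    fold_enrichment: float
    overlap: int
    n_significant: int
    n_targets: int
    n_universe: int

    @property
    def table(self) -> list[list[int]]:
        """2x2 contingency table [[in both, sig only], [target only, neither]]."""
        a = self.overlap
        b = self.n_significant - a
        c = self.n_targets - a
        d = self.n_universe - a - b - c
        return [[a, b], [c, d]]


def filter_targets(predictions: pd.DataFrame, k: int = 6) -> set[str]:
    """Genes predicted as targets by at least ``k`` programs.

    ``predictions`` is a genes x programs 0/1 (or boolean) matrix.
    """
    n_programs = predictions.shape[1]
    if k > n_programs:
        raise ValueError(f"k={k} exceeds number of programs ({n_programs})")
    vals = predictions.astype(bool)
    hits = vals.sum(axis=1)
    return set(predictions.index[hits >= k])


def enrich(significant: set, targets: set, universe: set) -> EnrichmentResult:
    """Hypergeometric enrichment of ``targets`` within ``significant`` genes.

    p = P(X >= overlap) with X ~ Hypergeom(population = |universe|,
    successes = |targets|, draws = |significant|).  Fold enrichment is the
    observed target fraction among significant genes over the universe-wide
    target fraction.
    """
    if not universe:
        raise ValueError("empty universe")
    if not significant:
        raise ValueError("empty significant set")
    if not significant <= universe:
        raise ValueError("significant genes must be a subset of the universe")
    if not targets <= universe:
        raise ValueError("target genes must be a subset of the universe")
    M, K, n = len(universe), len(targets), len(significant)
    overlap = len(significant & targets)
    p = float(hypergeom.sf(overlap - 1, M, K, n))
    expected = K / M
    fold = (overlap / n) / expected if expected > 0 else float("nan")
    return EnrichmentResult(
        p_value=p,
        fold_enrichment=float(fold),
        overlap=overlap,
        n_significant=n,
        n_targets=K,
        n_universe=M,
    )
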