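"""Drug exposure episodes from prescription-register purchase records.

A purchase record carries the purchase date and the amount dispensed in
defined daily doses (DDD, days of supply at one DDD per day).  Exposure
episodes ("medication periods") are reconstructed by:

* stretching each purchase's supply by a factor of 1.1 (imperfect adherence
  allowance),
* appending supply purchased before the current supply runs out after the
  current supply (carry-over), and
* bridging gaps of at most 15 days between consecutive supply intervals.

An episode lasting no more than three months (90 days, inclusive) is an
*early cessation* instance — the binary outcome of the pharmacogenetic
analysis.  Only drugs with at least 15 early-cessation instances are tested
individually; drug-group analyses pool all mapped drugs regardless of
frequency.

Dates are integer day offsets internally; the I/O layer converts calendar
dates.  Supply intervals are half-open [start, end).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "build_episodes",
    "derive_cessation",
    "derive_cessation_repurchase",
    "filter_drugs",
    "group_instances",
    "GROUP_LABELS",
]

logger = logging.getLogger(__name__)

GROUP_LABELS = (
    "cyp2c19_all",
    "ssri_all",
    "ssri_cyp2c19",
    "ssri_non_cyp2c19",
    "non_ssri_cyp2c19",
)


def build_episodes(
    register: pd.DataFrame,
    stretch: float = 1.1,
    gap_days: int = 15,
    window_end: float | None = None,
) -> pd.DataFrame:
    """Merge purchase records into exposure episodes.

    ``register`` needs columns ``individual_id``, ``atc_code``,
    ``purchase_day`` (numeric day offset) and ``ddd_amount``.  Records with
    non-positive DDD are rejected (logged).  Episodes whose supply runs past
    ``window_end`` are flagged ``censored`` (the true duration is unknown).

    Returns one row per episode: start_day, end_day, duration_days (end -
    start, gap days included), n_purchases, censored.
    """
    required = {"individual_id", "atc_code", "purchase_day", "ddd_amount"}
    missing = required - set(register.columns)
    if missing:
        raise ValueError(f"register missing columns: {sorted(missing)}")

    bad = register["ddd_amount"] <= 0
    if bad.any():
        logger.warning("rejected %d purchase records with non-positive DDD", bad.sum())
        register = register.loc[~bad]

    rows = []
    grouped = register.sort_values("purchase_day").groupby(
        ["individual_id", "atc_code"], sort=True
    )
    for (ind, drug), g in grouped:
        ep_start: float | None = None
        supply_end = 0.0
        n_purch = 0
        for day, ddd in zip(g["purchase_day"].to_numpy(), g["ddd_amount"].to_numpy()):
            supply = float(ddd) * stretch
            if ep_start is None:
                ep_start, supply_end, n_purch = float(day), float(day) + supply, 1
            elif day - supply_end <= gap_days:
                # carry-over: supply bought early starts when current supply ends
                supply_start = max(float(day), supply_end)
                supply_end = supply_start + supply
                n_purch += 1
            else:
                rows.append((ind, drug, ep_start, supply_end, n_purch))
                ep_start, supply_end, n_purch = float(day), float(day) + supply, 1
        if ep_start is not None:
            rows.append((ind, drug, ep_start, supply_end, n_purch))

    episodes = pd.DataFrame(
        rows, columns=["individual_id", "atc_code", "start_day", "end_day", "n_purchases"]
    )
    episodes["duration_days"] = episodes["end_day"] - episodes["start_day"]
    if window_end is None:
        episodes["censored"] = False
    else:
        episodes["censored"] = episodes["end_day"] > window_end
    return episodes


def derive_cessation(
    episodes: pd.DataFrame,
    cutoff_days: float = 90,
    covariates: pd.DataFrame | None = None,
    genotypes: pd.DataFrame | None = None,
    drug_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One cessation instance per (non-censored) episode.

    ``early_cessation`` is 1 iff the episode lasted at most ``cutoff_days``
    (inclusive).  If provided, ``covariates`` (indexed by individual, with a
    ``gender`` column) and ``genotypes`` (individuals x variants dosages) are
    joined; individuals without genotype data are excluded (logged).
    ``drug_map`` (indexed by ATC code with boolean ``is_ssri``/``cyp2c19``)
    attaches group tags.
    """
    inst = episodes.loc[~episodes["censored"]].copy()
    n_censored = int(episodes["censored"].sum())
    if n_censored:
        logger.info("excluded %d censored episodes from cessation outcomes", n_censored)
    inst["early_cessation"] = (inst["duration_days"] <= cutoff_days).astype(int)

    if covariates is not None:
        inst = inst.join(covariates[["gender"]], on="individual_id")
    if genotypes is not None:
        known = inst["individual_id"].isin(genotypes.index)
        if (~known).any():
            logger.warning(
                "excluded %d instances lacking genotype data", int((~known).sum())
            )
            inst = inst.loc[known]
        inst = inst.join(genotypes, on="individual_id")
    if drug_map is not None:
        inst = inst.join(drug_map[["is_ssri", "cyp2c19"]], on="atc_code")
    return inst.reset_index(drop=True)


def derive_cessation_repurchase(
    episodes: pd.DataFrame, register: pd.DataFrame, cutoff_days: float = 90
) -> pd.DataFrame:
    """Alternative outcome: no repurchase of *any* drug within the cut-off.

    Here early cessation means the individual made no further purchase of
    any psychoactive drug within ``cutoff_days`` after the episode's first
    purchase date.  Provided as a secondary reading of the three-month rule;
    the duration-based outcome of :func:`derive_cessation` is the default.
    """
    inst = episodes.loc[~episodes["censored"]].copy()
    purchases = register.groupby("individual_id")["purchase_day"].apply(
        lambda s: np.sort(s.to_numpy())
    )
    early = []
    for _, row in inst.iterrows():
        days = purchases.get(row["individual_id"], np.array([]))
        later = days[(days > row["start_day"]) & (days <= row["start_day"] + cutoff_days)]
        early.append(int(later.size == 0))
    inst["early_cessation"] = early
    return inst.reset_index(drop=True)


def filter_drugs(instances: pd.DataFrame, min_instances: int = 15) -> list[str]:
    """Drugs with at least ``min_instances`` early-cessation instances.

    These are analyzable as individual drugs; drugs below the threshold
    still contribute to their group analyses.
    """
    if instances.empty:
        return []
    counts = instances.groupby("atc_code")["early_cessation"].sum()
    return sorted(counts.index[counts >= min_instances])


def group_instances(
    instances: pd.DataFrame, drug_map: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Split instances into the five enzyme/class group tables.

    Groups: all CYP2C19-metabolized drugs; all SSRIs; SSRIs metabolized by
    CYP2C19; SSRIs not metabolized by CYP2C19; non-SSRIs metabolized by
    CYP2C19.  Every drug present must be mapped.
    """
    unmapped = sorted(set(instances["atc_code"]) - set(drug_map.index))
    if unmapped:
        raise ValueError(f"drugs missing from the drug-group map: {unmapped}")
    tagged = instances.join(
        drug_map[["is_ssri", "cyp2c19"]], on="atc_code", rsuffix="_map"
    )
    ssri = tagged["is_ssri" if "is_ssri" in tagged else "is_ssri_map"].astype(bool)
    cyp = tagged["cyp2c19" if "cyp2c19" in tagged else "cyp2c19_map"].astype(bool)
    # if instances already carried tags, prefer the map's
    if "is_ssri_map" in tagged:
        ssri = tagged["is_ssri_map"].astype(bool)
        cyp = tagged["cyp2c19_map"].astype(bool)
    base = instances.reset_index(drop=True)
    ssri = ssri.reset_index(drop=True)
    cyp = cyp.reset_index(drop=True)
    return {
        "cyp2c19_all": base.loc[cyp.to_numpy()],
        "ssri_all": base.loc[ssri.to_numpy()],
        "ssri_cyp2c19": base.loc[(ssri & cyp).to_numpy()],
        "ssri_non_cyp2c19": base.loc[(ssri & ~cyp).to_numpy()],
        "non_ssri_cyp2c19": base.loc[(~ssri & cyp).to_numpy()],
    }
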