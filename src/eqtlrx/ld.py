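"""Linkage disequilibrium from unphased genotypes.

Haplotype frequencies for a small number (<= 6) of biallelic loci are
estimated by an EM algorithm over the phase ambiguity of multiply
heterozygous individuals, exactly as done by standard LD software.  From the
two-locus haplotype frequencies the usual statistics follow:

    D   = p_AB - p_A * p_B
    D'  = |D| / D_max,  D_max = min(p_A p_b, p_a p_B) if D > 0
                               else min(p_A p_B, p_a p_b)
    r^2 = D^2 / (p_A p_a p_B p_b)

Alleles are coded 0/1 per locus and a haplotype is a tuple of allele codes;
for two loci the frequency vector is ordered (00, 01, 10, 11), i.e.
(AB, Ab, aB, ab) with "A"/"B" denoting allele 0.

A multi-locus "tag" haplotype can be converted to a per-individual dosage by
taking the posterior expected count of the target haplotype given the
unphased genotype (fractional by default, rounded also reported).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "LdStats",
    "em_hap_freqs",
    "ld_stats",
    "ld_between",
    "tag_haplotype_dosage",
    "haplotype_freqs_for_r2",
]

_EM_TOL = 1e-10
_EM_MAX_ITER = 1000


@dataclass
class LdStats:
    """Pairwise LD summary derived from two-locus haplotype frequencies."""

    hap_freqs: np.ndarray  # order (AB, Ab, aB, ab)
    D: float
    D_prime: float
    r2: float
    n: int
    monomorphic: bool = False


def _compatible_pairs(geno: tuple[int, ...]) -> list[tuple[int, int]]:
    """Unordered haplotype-index pairs consistent with an unphased genotype.

    Heterozygous loci are ambiguous; the first heterozygous locus is pinned
    to allele 0 on the first haplotype so each unordered pair appears once.
    """
    het = [i for i, g in enumerate(geno) if g == 1]
    base = [g // 2 for g in geno]  # 0 for g=0/1, 1 for g=2
    L = len(geno)

    def hap_index(alleles: list[int]) -> int:
        idx = 0
        for a in alleles:
            idx = (idx << 1) | a
        return idx

    if not het:
        h = hap_index(base)
        return [(h, h)]
    pairs = []
    free = het[1:]
    for assign in product((0, 1), repeat=len(free)):
        h1 = list(base)
        h2 = list(base)
        h1[het[0]], h2[het[0]] = 0, 1
        for locus, a in zip(free, assign):
            h1[locus], h2[locus] = a, 1 - a
        pairs.append((hap_index(h1), hap_index(h2)))
    return pairs


def _genotype_patterns(genos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique complete genotype rows and their multiplicities."""
    mask = ~np.isnan(genos).any(axis=1)
    g = genos[mask].astype(int)
    if g.size == 0:
        raise ValueError("no individuals with complete genotypes")
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("dosages must be 0, 1 or 2")
    uniq, counts = np.unique(g, axis=0, return_counts=True)
    return uniq, counts


def _em(
    patterns: np.ndarray,
    counts: np.ndarray,
    n_loci: int,
    freqs0: np.ndarray,
    tol: float = _EM_TOL,
    max_iter: int = _EM_MAX_ITER,
) -> tuple[np.ndarray, float]:
    """Run EM from a given start; returns (frequencies, log-likelihood)."""
    pair_lists = [_compatible_pairs(tuple(row)) for row in patterns]
    f = freqs0.copy()
    n = counts.sum()
    last_ll = -np.inf
    for _ in range(max_iter):
        hap_counts = np.zeros(2**n_loci)
        ll = 0.0
        for pairs, c in zip(pair_lists, counts):
            probs = np.array(
                [f[a] * f[b] * (2.0 if a != b else 1.0) for a, b in pairs]
            )
            tot = probs.sum()
            if tot <= 0:
                # start excluded a required haplotype; re-seed uniformly
                probs = np.ones(len(pairs))
                tot = probs.sum()
            w = probs / tot
            for (a, b), wi in zip(pairs, w):
                hap_counts[a] += c * wi
                hap_counts[b] += c * wi
            ll += c * np.log(tot)
        # likelihood must be monotone up to float noise
        if ll < last_ll - 1e-8:
            raise AssertionError("EM log-likelihood decreased")
        new_f = hap_counts / (2 * n)
        delta = np.max(np.abs(new_f - f))
        f = new_f
        if delta < tol:
            last_ll = ll
            break
        last_ll = ll
    return f, last_ll


def em_hap_freqs(
    *dosage_vectors: np.ndarray,
    n_restarts: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Maximum-likelihood haplotype frequencies from unphased dosages.

    Accepts one dosage vector per locus (or a single n x L matrix).  Missing
    genotypes (NaN) cause the individual to be dropped ("pairwise" deletion).
    For two loci a single EM start at linkage-equilibrium frequencies is
    used; for more loci a few random restarts guard against local optima.
    """
    if len(dosage_vectors) == 1 and np.asarray(dosage_vectors[0]).ndim == 2:
        genos = np.asarray(dosage_vectors[0], dtype=float)
    else:
        genos = np.column_stack([np.asarray(v, dtype=float) for v in dosage_vectors])
    n_loci = genos.shape[1]
    if n_loci > 6:
        raise ValueError("haplotype enumeration supported for at most 6 loci")
    if genos.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    patterns, counts = _genotype_patterns(genos)

    # linkage-equilibrium start from marginal allele frequencies
    n = counts.sum()
    p1 = (patterns * counts[:, None]).sum(axis=0) / (2 * n)  # allele-1 freq per locus
    le = np.ones(2**n_loci)
    for h in range(2**n_loci):
        for locus in range(n_loci):
            bit = (h >> (n_loci - 1 - locus)) & 1
            le[h] *= p1[locus] if bit else 1 - p1[locus]

    if n_restarts is None:
        n_restarts = 0 if n_loci <= 2 else 5
    best_f, best_ll = _em(patterns, counts, n_loci, le)
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        start = rng.dirichlet(np.ones(2**n_loci))
        f, ll = _em(patterns, counts, n_loci, start)
        if ll > best_ll + 1e-10:
            best_f, best_ll = f, ll
    return best_f


def ld_stats(hap_freqs: np.ndarray, n: int) -> LdStats:
    """D, D' and r^2 from a two-locus haplotype frequency vector (AB, Ab, aB, ab)."""
    f = np.asarray(hap_freqs, dtype=float)
    if f.shape != (4,):
        raise ValueError("two-locus statistics require 4 haplotype frequencies")
    if abs(f.sum() - 1) > 1e-9 or (f < -1e-12).any():
        raise ValueError("haplotype frequencies must be a probability vector")
    f_AB, f_Ab, f_aB = f[0], f[1], f[2]
    p_A = f_AB + f_Ab
    p_B = f_AB + f_aB
    p_a, p_b = 1 - p_A, 1 - p_B
    D = f_AB - p_A * p_B
    denom = p_A * p_a * p_B * p_b
    if denom <= 0:
        return LdStats(f, float(D), float("nan"), float("nan"), n, monomorphic=True)
    r2 = D * D / denom
    if D > 0:
        d_max = min(p_A * p_b, p_a * p_B)
    else:
        d_max = min(p_A * p_B, p_a * p_b)
    d_prime = 0.0 if d_max == 0 else abs(D) / d_max
    return LdStats(f, float(D), float(d_prime), float(r2), n)


def ld_between(g1: np.ndarray, g2: np.ndarray) -> LdStats:
    """EM haplotype frequencies and LD statistics for one variant pair.

    Individuals missing either genotype are dropped; ``n`` reports the
    number genotyped at both loci.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    mask = ~(np.isnan(g1) | np.isnan(g2))
    f = em_hap_freqs(g1[mask], g2[mask])
    return ld_stats(f, int(mask.sum()))


def tag_haplotype_dosage(
    genos: np.ndarray, target: str | tuple[int, ...], seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual expected count of a target multi-locus haplotype.

    ``genos`` is an n x L matrix of dosages (alleles coded 0/1 per locus,
    NaN allowed).  Haplotype frequencies are estimated by EM on the complete
    rows; each individual's dosage is the posterior expected number of
    copies of ``target`` given their unphased genotype.  Returns
    (fractional dosage, rounded dosage); individuals with missing genotypes
    get NaN.  If the target haplotype has estimated frequency 0 the dosage
    is 0 everywhere (a warning is emitted).
    """
    genos = np.asarray(genos, dtype=float)
    if isinstance(target, str):
        target_alleles = tuple(int(c) for c in target)
    else:
        target_alleles = tuple(int(a) for a in target)
    n_loci = genos.shape[1]
    if len(target_alleles) != n_loci:
        raise ValueError("target haplotype length does not match locus count")
    t_idx = 0
    for a in target_alleles:
        t_idx = (t_idx << 1) | a

    f = em_hap_freqs(genos, seed=seed)
    if f[t_idx] <= 0:
        import warnings

        warnings.warn("target haplotype not observed; dosage 0 for all individuals")

    frac = np.full(genos.shape[0], np.nan)
    complete = ~np.isnan(genos).any(axis=1)
    cache: dict[tuple[int, ...], float] = {}
    for i in np.nonzero(complete)[0]:
        key = tuple(int(g) for g in genos[i])
        if key not in cache:
            pairs = _compatible_pairs(key)
            probs = np.array([f[a] * f[b] * (2.0 if a != b else 1.0) for a, b in pairs])
            tot = probs.sum()
            if tot <= 0:
                cache[key] = 0.0
            else:
                w = probs / tot
                count = np.array(
                    [(a == t_idx) + (b == t_idx) for a, b in pairs], dtype=float
                )
                cache[key] = float(w @ count)
        frac[i] = cache[key]
    return frac, np.round(frac)


def haplotype_freqs_for_r2(p_a: float, p_b: float, r2: float) -> tuple[float, ...]:
    """Two-locus haplotype frequencies with given allele-0 frequencies and r^2.

    Solves r^2 = D^2 / (p_A p_a p_B p_b) for D > 0 and returns
    (AB, Ab, aB, ab).  Raises if the implied frequencies leave [0, 1].
    """
    if not (0 < p_a < 1 and 0 < p_b < 1 and 0 <= r2 <= 1):
        raise ValueError("allele frequencies in (0,1) and r2 in [0,1] required")
    D = np.sqrt(r2 * p_a * (1 - p_a) * p_b * (1 - p_b))
    freqs = (
        p_a * p_b + D,
        p_a * (1 - p_b) - D,
        (1 - p_a) * p_b - D,
        (1 - p_a) * (1 - p_b) + D,
    )
    if any(x < -1e-12 or x > 1 for x in freqs):
        raise ValueError(f"r2={r2} not attainable at these allele frequencies")
    return tuple(max(x, 0.0) for x in freqs)
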