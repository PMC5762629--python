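"""Within-population diversity: heterozygosity, F_IS, rarefied allelic
richness, Hardy-Weinberg exact tests and a null-allele moment estimator."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats

from ..types import MicrosatDataset


def _log_comb(n: float, k: float) -> float:
    if k < 0 or k > n:
        return -np.inf
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def heterozygosity(dataset: MicrosatDataset, population: str, locus: str):
    """Observed and Nei's unbiased expected heterozygosity.

    H_O is the heterozygous fraction among non-missing individuals; H_E is
    (2n/(2n-1)) * (1 - sum p_i^2) with n the number of typed individuals.
    Returns (nan, nan) when every call is missing.
    """
    geno = dataset.genotypes(population, locus)
    n = len(geno)
    if n == 0:
        return float("nan"), float("nan")
    ho = float(np.mean(geno[:, 0] != geno[:, 1]))
    counts = np.bincount(geno.ravel())[1:]
    p = counts[counts > 0] / (2 * n)
    he = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(p**2)))
    return ho, he


def _fis_components(dataset: MicrosatDataset, population: str, locus: str):
    """Per-locus Weir-Cockerham b+c and c sums for a single population.

    For one population the among-population term drops and the within-
    individual correlation is f = 1 - sum(c) / sum(b + c) with, per allele,
    b = (n/(n-1)) * (p(1-p) - (2n-1)/(4n) * h) and c = h/2.
    """
    geno = dataset.genotypes(population, locus)
    n = len(geno)
    if n < 2:
        return 0.0, 0.0
    counts = Counter(geno.ravel().tolist())
    bc_sum = c_sum = 0.0
    for allele, copies in counts.items():
        p = copies / (2 * n)
        h = float(np.mean((geno == allele).sum(axis=1) == 1))
        b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        c = h / 2.0
        bc_sum += b + c
        c_sum += c
    return bc_sum, c_sum


@dataclass
class FisResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_loci: int


def fis(
    dataset: MicrosatDataset,
    population: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> FisResult:
    """Multilocus inbreeding coefficient with a bootstrap-over-loci 95% CI.

    Ratio-of-sums across loci of the Weir-Cockerham within-population
    components.  With a single informative locus the CI is degenerate
    (equal to the point estimate).
    """
    comps = np.array(
        [_fis_components(dataset, population, locus) for locus in dataset.loci]
    )
    informative = comps[:, 0] > 0
    comps = comps[informative]
    if len(comps) == 0:
        return FisResult(float("nan"), float("nan"), float("nan"), 0)
    point = 1.0 - comps[:, 1].sum() / comps[:, 0].sum()
    if len(comps) == 1:
        return FisResult(point, point, point, 1)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(comps), size=(n_boot, len(comps)))
    bc = comps[idx, 0].sum(axis=1)
    c = comps[idx, 1].sum(axis=1)
    boots = 1.0 - c / bc
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return FisResult(float(point), float(lo), float(hi), len(comps))


def allelic_richness(
    dataset: MicrosatDataset, population: str, locus: str, g: int
) -> float:
    """Expected number of distinct alleles in a rarefied sample of g copies.

    A_R(g) = sum_i [1 - C(N - N_i, g) / C(N, g)] over alleles i, with N the
    non-missing gene copies and N_i the copies of allele i; exact
    hypergeometric combinatorics in log space.
    """
    counts = dataset.allele_counts(population, locus)
    n_copies = sum(counts.values())
    if g < 1:
        raise ValueError("rarefaction size g must be >= 1")
    if g > n_copies:
        raise ValueError(f"g={g} exceeds the {n_copies} gene copies available")
    log_cn = _log_comb(n_copies, g)
    return float(
        sum(1.0 - np.exp(_log_comb(n_copies - ni, g) - log_cn) for ni in counts.values())
    )


def _presence_prob(counts: Counter, allele: int, g: int) -> float:
    """Q(g): probability the allele appears in a rarefied sample of g copies."""
    n = sum(counts.values())
    ni = counts.get(allele, 0)
    if ni == 0:
        return 0.0
    return 1.0 - float(np.exp(_log_comb(n - ni, g) - _log_comb(n, g)))


def private_allelic_richness(
    dataset: MicrosatDataset, population: str, locus: str, g: int
) -> float:
    """Rarefied private allelic richness (Kalinowski's estimator).

    Sum over alleles of P(present in g copies from the focal population) *
    P(absent from rarefied samples of g copies from every other population).
    Requires every population to have >= g copies at the locus.
    """
    pops = dataset.populations
    counts = {p: dataset.allele_counts(p, locus) for p in pops}
    for p, c in counts.items():
        if sum(c.values()) < g:
            raise ValueError(f"population {p!r} has fewer than g={g} copies at {locus!r}")
    total = 0.0
    for allele in counts[population]:
        q_focal = _presence_prob(counts[population], allele, g)
        absent_elsewhere = 1.0
        for other in pops:
            if other != population:
                absent_elsewhere *= 1.0 - _presence_prob(counts[other], allele, g)
        total += q_focal * absent_elsewhere
    return total


def min_copies(dataset: MicrosatDataset, locus: str) -> int:
    """Smallest per-population gene-copy count at a locus (rarefaction base)."""
    return min(
        sum(dataset.allele_counts(p, locus).values()) for p in dataset.populations
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte Carlo) and null alleles
# ---------------------------------------------------------------------------

def _log_genotype_prob(geno: np.ndarray) -> float:
    """Levene's conditional log-probability of a genotype array given its
    allele counts: 2^H * n! * prod(c_a!) / ((2n)! * prod(n_gg!))."""
    n = len(geno)
    allele_counts = Counter(geno.ravel().tolist())
    geno_counts = Counter(map(tuple, np.sort(geno, axis=1).tolist()))
    n_het = sum(1 for g in geno if g[0] != g[1])
    logp = n_het * np.log(2.0) + lgamma(n + 1) - lgamma(2 * n + 1)
    logp += sum(lgamma(c + 1) for c in allele_counts.values())
    logp -= sum(lgamma(c + 1) for c in geno_counts.values())
    return float(logp)


def hwe_test(
    dataset: MicrosatDataset,
    population: str,
    locus: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Monte Carlo exact Hardy-Weinberg test (probability-ordering).

    The statistic is the conditional probability of the genotype array given
    the allele counts; p is the share of gene-copy shuffles whose array is
    no more probable than the observed one.  Monomorphic data give p = 1.
    """
    geno = dataset.genotypes(population, locus)
    if len(geno) == 0 or len(set(geno.ravel().tolist())) < 2:
        return 1.0
    obs = _log_genotype_prob(geno)
    rng = np.random.default_rng(seed)
    copies = geno.ravel().copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(copies)
        perm = copies.reshape(-1, 2)
        if _log_genotype_prob(perm) <= obs + 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def null_allele_estimate(
    dataset: MicrosatDataset, population: str, locus: str
) -> float:
    """Chakraborty's moment estimator of null-allele frequency,
    r = (H_E - H_O) / (H_E + H_O).  NaN when H_E + H_O = 0."""
    ho, he = heterozygosity(dataset, population, locus)
    if not np.isfinite(ho) or he + ho == 0:
        return float("nan")
    return (he - ho) / (he + ho)


def screen_loci(
    dataset: MicrosatDataset,
    null_threshold: float = 0.15,
    hwe_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-locus QC: mean null-allele estimate across populations and
    Bonferroni-corrected Hardy-Weinberg deviations.

    A locus is flagged for exclusion when its mean Chakraborty estimate
    exceeds ``null_threshold`` or any population deviates from HW after
    Bonferroni correction across the (population x locus) family.
    """
    pops = dataset.populations
    n_tests = len(pops) * len(dataset.loci)
    rows = []
    for locus in dataset.loci:
        r_vals = [null_allele_estimate(dataset, p, locus) for p in pops]
        r_mean = float(np.nanmean(r_vals)) if np.isfinite(r_vals).any() else float("nan")
        p_vals = [
            hwe_test(dataset, p, locus, n_perm=n_perm, seed=seed + 31 * k)
            for k, p in enumerate(pops)
        ]
        min_adj = min(1.0, min(p_vals) * n_tests)
        rows.append(
            dict(
                locus=locus,
                mean_null_freq=r_mean,
                min_hwe_p_bonferroni=min_adj,
                exclude=bool(
                    (np.isfinite(r_mean) and r_mean > null_threshold)
                    or min_adj < hwe_alpha
                ),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Table-1-shaped population summary
# ---------------------------------------------------------------------------

def diversity_summary(
    dataset: MicrosatDataset,
    rarefaction_g: int | None = None,
    bottleneck_kwargs: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-population diversity table: N, H_E, H_O, F_IS (with CI), rarefied
    A_R and A_PR, and (optionally) the bottleneck heterozygosity-excess test.

    ``rarefaction_g`` defaults to the smallest per-locus copy count across
    populations (evaluated per locus).  Pass ``bottleneck_kwargs`` (even an
    empty dict) to run the bottleneck test; ``None`` skips it.
    """
    from .bottleneck import bottleneck_test

    rows = []
    for k, pop in enumerate(dataset.populations):
        hs = np.array([heterozygosity(dataset, pop, l) for l in dataset.loci])
        fis_res = fis(dataset, pop, seed=seed + k)
        ar, apr = [], []
        for locus in dataset.loci:
            g = rarefaction_g if rarefaction_g is not None else min_copies(dataset, locus)
            own = sum(dataset.allele_counts(pop, locus).values())
            if g < 1 or own < g:
                continue
            ar.append(allelic_richness(dataset, pop, locus, g))
            try:
                apr.append(private_allelic_richness(dataset, pop, locus, g))
            except ValueError:
                pass  # some other population too small at this locus; skip
        row = dict(
            population=pop,
            region=dataset.region_of(pop),
            N=len(dataset.indices_of(pop)),
            H_O=float(np.nanmean(hs[:, 0])),
            H_E=float(np.nanmean(hs[:, 1])),
            F_IS=fis_res.estimate,
            F_IS_low=fis_res.ci_low,
            F_IS_high=fis_res.ci_high,
            A_R=float(np.mean(ar)) if ar else float("nan"),
            A_PR=float(np.mean(apr)) if apr else float("nan"),
        )
        if bottleneck_kwargs is not None:
            bt = bottleneck_test(dataset, pop, seed=seed + 101 * k, **bottleneck_kwargs)
            row["bottleneck_p"] = bt.wilcoxon_p
            row["mode_shift"] = bt.mode_shift
        rows.append(row)
    return pd.DataFrame(rows)
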