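"""Weir & Cockerham's theta: multilocus, bootstrap CI over loci, and a
pairwise matrix with individual-permutation significance."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..types import MicrosatDataset, PairwiseMatrix


def _locus_components(genos: list[np.ndarray]) -> tuple[float, float, float]:
    """Summed (a, b, c) variance components over alleles at one locus.

    ``genos``: one (n_i, 2) non-missing genotype array per population.
    Implements the unequal-sample-size moment estimator with, per allele,
    the among-population (a), among-individual-within-population (b) and
    within-individual (c) components; theta = a / (a + b + c).
    Populations with no data at the locus are dropped; returns zeros when
    fewer than two populations remain or the locus is monomorphic.
    """
    genos = [g for g in genos if len(g) > 0]
    r = len(genos)
    if r < 2:
        return 0.0, 0.0, 0.0
    n = np.array([len(g) for g in genos], dtype=float)
    alleles = sorted({int(a) for g in genos for a in g.ravel()})
    if len(alleles) < 2:
        return 0.0, 0.0, 0.0
    nbar = n.mean()
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p = np.array([np.mean(g == allele) for g in genos])  # copy frequency
        h = np.array([np.mean((g == allele).sum(axis=1) == 1) for g in genos])
        pbar = np.sum(n * p) / (r * nbar)
        s2 = np.sum(n * (p - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(n * h) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return float(a_sum), float(b_sum), float(c_sum)


@dataclass
class FstResult:
    theta: float
    ci_low: float
    ci_high: float
    per_locus: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    @property
    def per_locus_theta(self) -> dict[str, float]:
        return {
            l: (a / (a + b + c) if (a + b + c) != 0 else float("nan"))
            for l, (a, b, c) in self.per_locus.items()
        }


def weir_cockerham_theta(
    dataset: MicrosatDataset,
    populations: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> FstResult:
    """Multilocus theta as the ratio of summed components, with a 95%
    bootstrap-over-loci CI.  Negative estimates are reported as computed.

    Monomorphic loci contribute nothing (0/0) and are excluded from the
    sums and the bootstrap.
    """
    pops = populations if populations is not None else dataset.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    per_locus = {}
    for locus in dataset.loci:
        comp = _locus_components([dataset.genotypes(p, locus) for p in pops])
        if comp != (0.0, 0.0, 0.0):
            per_locus[locus] = comp
    if not per_locus:
        raise ValueError("no polymorphic locus shared by the populations")
    comps = np.array(list(per_locus.values()))
    theta = comps[:, 0].sum() / comps.sum()
    if len(comps) > 1 and n_boot > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(comps), size=(n_boot, len(comps)))
        num = comps[idx, 0].sum(axis=1)
        den = comps[idx, :].sum(axis=(1, 2))
        boots = np.divide(num, den, out=np.full(n_boot, np.nan), where=den != 0)
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    else:
        lo = hi = theta
    return FstResult(float(theta), float(lo), float(hi), per_locus)


def _theta_two_groups(genos_a: list[np.ndarray], genos_b: list[np.ndarray]) -> float:
    """Multilocus theta for two populations given per-locus genotype arrays."""
    a = b = c = 0.0
    for ga, gb in zip(genos_a, genos_b):
        ca, cb, cc = _locus_components([ga, gb])
        a, b, c = a + ca, b + cb, c + cc
    tot = a + b + c
    return a / tot if tot != 0 else float("nan")


def pairwise_theta(
    dataset: MicrosatDataset,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[PairwiseMatrix, PairwiseMatrix]:
    """Pairwise theta matrix and one-tailed permutation p-values.

    Significance permutes individuals between the two populations; the
    identity arrangement is included in both numerator and denominator.
    """
    pops = dataset.populations
    n = len(pops)
    theta = np.zeros((n, n))
    pvals = np.zeros((n, n))
    rng = np.random.default_rng(seed)
    # pre-extract genotype rows once
    rows = {p: dataset.indices_of(p) for p in pops}
    for i in range(n):
        for j in range(i + 1, n):
            idx = np.concatenate([rows[pops[i]], rows[pops[j]]])
            ni = len(rows[pops[i]])
            calls = dataset.calls[idx]  # (n_ind, n_loci, 2)

            def split_theta(order: np.ndarray) -> float:
                ga = [
                    calls[order[:ni], l][np.all(calls[order[:ni], l] > 0, axis=1)]
                    for l in range(len(dataset.loci))
                ]
                gb = [
                    calls[order[ni:], l][np.all(calls[order[ni:], l] > 0, axis=1)]
                    for l in range(len(dataset.loci))
                ]
                return _theta_two_groups(ga, gb)

            order = np.arange(len(idx))
            obs = split_theta(order)
            theta[i, j] = theta[j, i] = obs
            if n_perm > 0:
                hits = 1  # identity permutation
                for _ in range(n_perm):
                    rng.shuffle(order)
                    t = split_theta(order)
                    if np.isfinite(t) and t >= obs - 1e-15:
                        hits += 1
                pvals[i, j] = pvals[j, i] = hits / (n_perm + 1)
    np.fill_diagonal(pvals, 0.0)
    return PairwiseMatrix(list(pops), theta), PairwiseMatrix(list(pops), pvals)
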