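"""Analysis of molecular variance (allele-identity AMOVA) with a nested
group / population-within-group / within-population decomposition."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import MicrosatDataset


def _ssd(copy_counts: np.ndarray) -> float:
    """Sum of squared differences within a set of gene copies, divided by set
    size, for the 0/1 allele-identity distance: (m - sum c_a^2 / m) / 2."""
    m = copy_counts.sum()
    if m == 0:
        return 0.0
    return float((m - np.sum(copy_counts.astype(float) ** 2) / m) / 2.0)


@dataclass
class AmovaResult:
    sigma2_among_groups: float
    sigma2_among_pops: float
    sigma2_within: float
    percent_among_groups: float
    percent_among_pops: float
    percent_within: float
    phi_ct: float  # groups / total
    phi_sc: float  # pops within groups
    phi_st: float  # pops+groups / total
    p_among_groups: float | None = None
    p_among_pops: float | None = None
    p_within: float | None = None

    @property
    def percentages(self) -> tuple[float, float, float]:
        return (self.percent_among_groups, self.percent_among_pops, self.percent_within)


def _components(
    counts: np.ndarray, pop_group: np.ndarray
) -> tuple[float, float, float]:
    """Variance components for one locus.

    ``counts``: (n_pops, n_alleles) gene-copy counts; ``pop_group``: group
    index per population.  Returns (sigma2_a groups, sigma2_b pops-in-groups,
    sigma2_c within-pops); negative components are reported as computed.
    """
    counts = np.asarray(counts, dtype=float)
    P = counts.shape[0]
    groups = np.unique(pop_group)
    G = len(groups)
    N_p = counts.sum(axis=1)
    N = N_p.sum()
    if N == 0 or P < 2:
        return 0.0, 0.0, 0.0

    ssd_wp = sum(_ssd(counts[p]) for p in range(P))
    group_counts = np.stack([counts[pop_group == g].sum(axis=0) for g in groups])
    N_g = group_counts.sum(axis=1)
    ssd_wg = sum(_ssd(group_counts[k]) for k in range(G))
    ssd_total = _ssd(counts.sum(axis=0))

    df_wp = N - P
    df_ap = P - G
    df_ag = G - 1
    ms_wp = ssd_wp / df_wp if df_wp > 0 else 0.0
    sigma_c = ms_wp
    sum_np2_over_ng = sum(
        np.sum(N_p[pop_group == g] ** 2) / N_g[k] for k, g in enumerate(groups) if N_g[k] > 0
    )
    if df_ap > 0:
        ms_ap = (ssd_wg - ssd_wp) / df_ap
        n_coef = (N - sum_np2_over_ng) / df_ap
        sigma_b = (ms_ap - sigma_c) / n_coef if n_coef > 0 else 0.0
    else:
        sigma_b = 0.0
    if df_ag > 0:
        ms_ag = (ssd_total - ssd_wg) / df_ag
        n_prime = (sum_np2_over_ng - np.sum(N_p**2) / N) / df_ag
        n_dprime = (N - np.sum(N_g**2) / N) / df_ag
        sigma_a = (ms_ag - sigma_c - n_prime * sigma_b) / n_dprime if n_dprime > 0 else 0.0
    else:
        sigma_a = 0.0
    return float(sigma_a), float(sigma_b), float(sigma_c)


def _count_matrix(dataset: MicrosatDataset, pops: list[str]) -> list[np.ndarray]:
    """Per-locus (n_pops, n_alleles) gene-copy count matrices."""
    out = []
    for locus in dataset.loci:
        per_pop = [dataset.allele_counts(p, locus) for p in pops]
        alleles = sorted({a for c in per_pop for a in c})
        mat = np.array([[c.get(a, 0) for a in alleles] for c in per_pop], dtype=float)
        out.append(mat)
    return out


def amova(
    dataset: MicrosatDataset,
    groups: dict[str, list[str]] | None = None,
    n_perm: int = 10000,
    seed: int = 0,
) -> AmovaResult:
    """Three-level AMOVA over gene copies, components summed across loci.

    ``groups`` maps group name -> populations (default: the dataset's
    region labels).  With a single group the among-group level is dropped
    and the result is the two-level decomposition.  Significance at each
    level is by seeded permutation: populations across groups (among
    groups), individuals across populations within groups (among
    populations), and individuals across all populations (within).
    """
    if groups is None:
        groups = dataset.regions
    pops = [p for ps in groups.values() for p in ps]
    pop_group = np.array(
        [k for k, ps in enumerate(groups.values()) for _ in ps], dtype=int
    )
    count_mats = _count_matrix(dataset.subset(populations=pops), pops)

    def total_components(mats) -> tuple[float, float, float]:
        acc = np.zeros(3)
        for m in mats:
            acc += _components(m, pop_group)
        return tuple(acc)

    sigma_a, sigma_b, sigma_c = total_components(count_mats)
    total = sigma_a + sigma_b + sigma_c
    pct = (
        (100 * sigma_a / total, 100 * sigma_b / total, 100 * sigma_c / total)
        if total != 0
        else (0.0, 0.0, 100.0)
    )
    phi_ct = sigma_a / total if total else 0.0
    phi_st = (sigma_a + sigma_b) / total if total else 0.0
    denom_sc = sigma_b + sigma_c
    phi_sc = sigma_b / denom_sc if denom_sc else 0.0

    p_ag = p_ap = p_w = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        sub = dataset.subset(populations=pops)
        pop_of = np.array([pops.index(ind.population) for ind in sub.individuals])
        group_of_ind = pop_group[pop_of]

        def stats_for(assign: np.ndarray) -> tuple[float, float, float]:
            mats = []
            for l in range(len(sub.loci)):
                calls = sub.calls[:, l, :]
                ok = (calls > 0).all(axis=1)
                alleles = np.unique(calls[ok])
                mat = np.zeros((len(pops), len(alleles)))
                for p in range(len(pops)):
                    sel = calls[ok & (assign == p)]
                    if len(sel):
                        mat[p] = (sel[..., None] == alleles).sum(axis=(0, 1))
                mats.append(mat)
            sa, sb, sc = total_components(mats)
            t = sa + sb + sc
            return (
                sa / t if t else 0.0,
                (sb / (sb + sc)) if (sb + sc) else 0.0,
                ((sa + sb) / t) if t else 0.0,
            )

        # among-pops-within-groups: shuffle individuals within their group
        hits_ap = 1
        for _ in range(n_perm):
            assign = pop_of.copy()
            for g in np.unique(group_of_ind):
                sel = np.where(group_of_ind == g)[0]
                assign[sel] = pop_of[rng.permutation(sel)]
            if stats_for(assign)[1] >= phi_sc - 1e-15:
                hits_ap += 1
        p_ap = hits_ap / (n_perm + 1)

        # within (phi_st analog): shuffle individuals across all populations
        hits_w = 1
        for _ in range(n_perm):
            assign = pop_of[rng.permutation(len(pop_of))]
            if stats_for(assign)[2] >= phi_st - 1e-15:
                hits_w += 1
        p_w = hits_w / (n_perm + 1)

        # among groups: permute whole populations among groups
        if len(groups) > 1:
            hits_ag = 1
            for _ in range(n_perm):
                perm = rng.permutation(len(pops))
                pg = pop_group[perm]
                acc = np.zeros(3)
                for m in count_mats:
                    acc += _components(m, pg)
                t = acc.sum()
                if (acc[0] / t if t else 0.0) >= phi_ct - 1e-15:
                    hits_ag += 1
            p_ag = hits_ag / (n_perm + 1)

    return AmovaResult(
        sigma_a, sigma_b, sigma_c, *pct, phi_ct, phi_sc, phi_st, p_ag, p_ap, p_w
    )
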