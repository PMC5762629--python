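"""Synthetic data generators with known ground truth.

Every downstream stage in the package is exercised on data from this module,
so each estimator has a parameter-recovery test: genotypes come from a
Balding-Nichols island model (target F_ST is an explicit parameter) or a
linear stepping-stone chain (isolation by distance by construction);
phenotypes from a Gaussian random-intercept model with known between- and
within-population variances; assay logs from Poisson event processes; and
reflectance spectra from flat curves along a brightness gradient.

All generators are deterministic under a fixed seed.  Per-component RNG
streams are derived from one integer seed with ``numpy.random.default_rng``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .types import (
    AssayEvent,
    AssayLog,
    Individual,
    MicrosatDataset,
    PhenotypeTable,
    SpectrumTable,
    WAVELENGTHS,
)

#: region labels used when emulating the four-region study design
DEFAULT_REGIONS = ("South", "Negev", "Center", "North")


def _assign_regions(n_pops: int) -> list[str]:
    """Split populations into four contiguous blocks from south to north."""
    edges = np.linspace(0, n_pops, len(DEFAULT_REGIONS) + 1).round().astype(int)
    out = []
    for k, name in enumerate(DEFAULT_REGIONS):
        out.extend([name] * (edges[k + 1] - edges[k]))
    return out


@dataclass
class GenoSimSpec:
    """Parameters of the genotype simulator.

    Defaults emulate the study regime: 14 populations x 20 diploid
    individuals at 8 microsatellite loci with 4-28 alleles per locus and a
    global differentiation around F = 0.008.  The Dirichlet concentration
    0.3 gives the skewed (rare-allele-heavy) frequency spectra typical of
    microsatellite surveys and puts expected heterozygosity in the
    mid-0.7s for the default allele-count range.
    """

    n_pops: int = 14
    n_per_pop: int = 20
    n_loci: int = 8
    alleles_per_locus: tuple[int, int] = (4, 28)
    dirichlet_conc: float = 0.3
    model: str = "island"  # island | stepping_stone
    F: float = 0.008
    step_delta: float = 0.01
    panmictic: bool = False
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_pop < 2:
            raise ValueError("n_per_pop must be >= 2")
        if self.model not in ("island", "stepping_stone"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "island" and not self.panmictic and not 0 < self.F < 1:
            raise ValueError("island model needs F in (0, 1); use panmictic=True for F=0")
        if self.model == "stepping_stone" and not 0 < self.step_delta < 1:
            raise ValueError("stepping-stone drift delta must be in (0, 1)")


def simulate_genotypes(spec: GenoSimSpec) -> MicrosatDataset:
    """Draw a diploid microsatellite dataset under the spec's model.

    Island model (Balding-Nichols): per-locus population frequencies are
    Dirichlet(p_bar * (1-F)/F) around ancestral frequencies p_bar, so the
    expected Wright F_ST equals ``spec.F``.  Stepping-stone: population j+1
    frequencies drift from population j with per-step variance
    delta * p * (1-p), giving distance-correlated divergence along the line.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.alleles_per_locus
    n_alleles = rng.integers(lo, hi + 1, size=spec.n_loci)
    regions = _assign_regions(spec.n_pops)

    individuals = []
    for p in range(spec.n_pops):
        for i in range(spec.n_per_pop):
            sex = "M" if (i % 2 == 0) else "F"
            individuals.append(
                Individual(
                    id=f"P{p + 1:02d}_I{i + 1:03d}",
                    population=f"pop{p + 1:02d}",
                    region=regions[p],
                    sex=sex,
                )
            )

    calls = np.zeros((len(individuals), spec.n_loci, 2), dtype=np.int64)
    for j in range(spec.n_loci):
        k = int(n_alleles[j])
        ancestral = rng.dirichlet(np.full(k, spec.dirichlet_conc))
        ancestral = np.clip(ancestral, 1e-4, None)
        ancestral /= ancestral.sum()
        if spec.panmictic:
            pop_freqs = np.tile(ancestral, (spec.n_pops, 1))
        elif spec.model == "island":
            conc = ancestral * (1.0 - spec.F) / spec.F
            pop_freqs = rng.dirichlet(conc, size=spec.n_pops)
        else:  # stepping stone along the population line
            pop_freqs = np.empty((spec.n_pops, k))
            p = ancestral
            for q in range(spec.n_pops):
                pop_freqs[q] = p
                conc = p * (1.0 - spec.step_delta) / spec.step_delta
                p = rng.dirichlet(conc)
                # keep frequencies off the absorbing boundaries
                p = np.clip(p, 1e-3, 1 - 1e-3)
                p /= p.sum()
        for q in range(spec.n_pops):
            rows = slice(q * spec.n_per_pop, (q + 1) * spec.n_per_pop)
            copies = rng.choice(k, size=(spec.n_per_pop, 2), p=pop_freqs[q])
            calls[rows, j, :] = copies + 1  # allele codes are 1-based
    if spec.missing_rate > 0:
        mask = rng.random((len(individuals), spec.n_loci)) < spec.missing_rate
        calls[mask] = 0
    return MicrosatDataset(individuals, [f"L{j + 1}" for j in range(spec.n_loci)],
                           np.sort(calls, axis=2))


@dataclass
class PhenoSimSpec:
    """Gaussian random-intercept phenotype model with known variances."""

    n_pops: int = 14
    n_per_pop: int = 20
    sigma2_between: float = 1.0
    sigma2_within: float = 1.0
    grand_mean: float = 0.0
    sex_effect: float = 0.0  # added to males
    year_effect: float = 0.0  # added per year unit above the base year
    latitude_slope: float = 0.0  # deterministic trend along the population line
    trait: str = "trait"
    seed: int = 0

    def __post_init__(self):
        if self.sigma2_between < 0 or self.sigma2_within <= 0:
            raise ValueError("need sigma2_between >= 0 and sigma2_within > 0")


#: pseudo-latitudes assigned to populations along the sampling line (deg N)
LAT_SOUTH, LAT_NORTH = 29.6, 33.2


def population_latitudes(n_pops: int) -> np.ndarray:
    return np.linspace(LAT_SOUTH, LAT_NORTH, n_pops)


def simulate_phenotypes(
    spec: PhenoSimSpec, dataset: MicrosatDataset | None = None
) -> PhenotypeTable:
    """value = grand mean + pop effect + latitude trend + sex + year + residual.

    Population effects are N(0, sigma2_between); residuals N(0, sigma2_within).
    If a genotype dataset is given, its individuals (ids, populations,
    regions, sexes) are reused so the phenotype and genotype tables align.
    """
    rng = np.random.default_rng(spec.seed)
    if dataset is not None:
        inds = dataset.individuals
        pops = dataset.populations
    else:
        regions = _assign_regions(spec.n_pops)
        inds = [
            Individual(
                id=f"P{p + 1:02d}_I{i + 1:03d}",
                population=f"pop{p + 1:02d}",
                region=regions[p],
                sex="M" if i % 2 == 0 else "F",
            )
            for p in range(spec.n_pops)
            for i in range(spec.n_per_pop)
        ]
        pops = [f"pop{p + 1:02d}" for p in range(spec.n_pops)]
    lat = dict(zip(pops, population_latitudes(len(pops))))
    pop_effect = dict(zip(pops, rng.normal(0.0, np.sqrt(spec.sigma2_between), len(pops))))
    years = rng.integers(0, 3, size=len(inds))
    resid = rng.normal(0.0, np.sqrt(spec.sigma2_within), len(inds))
    rows = []
    for ind, yr, e in zip(inds, years, resid):
        value = (
            spec.grand_mean
            + pop_effect[ind.population]
            + spec.latitude_slope * (lat[ind.population] - LAT_SOUTH)
            + (spec.sex_effect if ind.sex == "M" else 0.0)
            + spec.year_effect * yr
            + e
        )
        rows.append(
            dict(individual=ind.id, population=ind.population, region=ind.region,
                 sex=ind.sex, year=2013 + int(yr), trait=spec.trait, value=value)
        )
    return PhenotypeTable(pd.DataFrame(rows))


def true_pst(spec: PhenoSimSpec, ratio_c_h2: float = 1.0) -> float:
    """Plug-in phenotypic differentiation implied by the simulation truth."""
    num = ratio_c_h2 * spec.sigma2_between
    return num / (num + 2.0 * spec.sigma2_within)


def simulate_equilibrium_genotypes(
    n_individuals: int = 20,
    n_loci: int = 8,
    theta: float = 3.0,
    population: str = "pop01",
    seed: int = 0,
) -> MicrosatDataset:
    """One population at infinite-alleles mutation-drift equilibrium.

    Gene-copy allele configurations are drawn from the Ewens sampling
    formula by Hoppe's urn (a fresh allele with probability theta/(theta+i)
    at the i-th draw) and paired at random into diploid genotypes;
    monomorphic draws are rejected.  This is the null population for
    calibrating the bottleneck heterozygosity-excess test, generated by a
    route independent of the coalescent machinery the test itself uses.
    """
    rng = np.random.default_rng(seed)
    n_copies = 2 * n_individuals
    calls = np.zeros((n_individuals, n_loci, 2), dtype=np.int64)
    for j in range(n_loci):
        while True:
            labels = np.empty(n_copies, dtype=np.int64)
            nxt = 1
            for i in range(n_copies):
                if rng.random() < theta / (theta + i):
                    labels[i] = nxt
                    nxt += 1
                else:
                    labels[i] = labels[rng.integers(0, i)]
            if nxt > 2:  # polymorphic
                break
        labels = labels[rng.permutation(n_copies)]
        calls[:, j, 0] = labels[:n_individuals]
        calls[:, j, 1] = labels[n_individuals:]
    inds = [
        Individual(id=f"EQ_I{i + 1:03d}", population=population)
        for i in range(n_individuals)
    ]
    return MicrosatDataset(inds, [f"L{j + 1}" for j in range(n_loci)],
                           np.sort(calls, axis=2))


# ---------------------------------------------------------------------------
# Behavioral assays
# ---------------------------------------------------------------------------

DEFAULT_RATES = {"hop": 3.0, "flight": 0.6, "move": 1.0,
                 "enter_quarter": 0.5, "land_perch": 0.4}


def simulate_assay(
    n_birds: int,
    rates: dict[str, float] | None = None,
    neophobia_bias: float = 0.5,
    center_fraction: float = 0.2,
    duration: float = 15.0,
    population: str = "pop01",
    seed: int = 0,
) -> list[AssayLog]:
    """Poisson event logs for a cohort of birds.

    ``rates`` are events per minute; perch landings choose a decorated perch
    with probability ``neophobia_bias`` (1.0 = always decorated);
    ``center_fraction`` of the assay is spent in the center, as one block.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rates = {**DEFAULT_RATES, **(rates or {})}
    rng = np.random.default_rng(seed)
    logs = []
    for b in range(n_birds):
        events: list[AssayEvent] = []
        for kind, rate in rates.items():
            n = rng.poisson(rate * duration)
            for t in np.sort(rng.uniform(0, duration, n)):
                if kind == "enter_quarter":
                    arg = int(rng.integers(1, 5))
                elif kind == "land_perch":
                    decorated = rng.random() < neophobia_bias
                    arg = int(rng.choice([1, 2, 3] if decorated else [4, 5, 6]))
                else:
                    arg = None
                events.append(AssayEvent(float(t), kind, arg))
        if center_fraction > 0:
            span = center_fraction * duration
            start = float(rng.uniform(0, duration - span))
            events.append(AssayEvent(start, "enter_center"))
            events.append(AssayEvent(start + span, "leave_center"))
        events.sort(key=lambda ev: ev.time)
        logs.append(
            AssayLog(
                assay_id=f"assay{seed}_{b + 1:03d}",
                bird_id=f"bird{seed}_{b + 1:03d}",
                population=population,
                duration=duration,
                events=events,
            )
        )
    return logs


def simulate_spectra(
    n: int,
    gradient: tuple[float, float] = (0.2, 0.8),
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[SpectrumTable, np.ndarray]:
    """Flat reflectance spectra at levels interpolated along a gradient.

    Returns the table and the gradient positions in [0, 1] (ground truth for
    regression recovery tests).  Noise is per-wavelength Gaussian, clipped
    at zero.
    """
    rng = np.random.default_rng(seed)
    pos = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1)
    levels = gradient[0] + pos * (gradient[1] - gradient[0])
    spectra = levels[:, None] + rng.normal(0.0, noise_sd, (n, len(WAVELENGTHS)))
    spectra = np.clip(spectra, 0.0, None)
    return SpectrumTable([f"s{i + 1:03d}" for i in range(n)], spectra), pos


def spec_as_dict(spec) -> dict:
    """Echo a generator spec into a JSON/YAML-serializable dict."""
    d = asdict(spec)
    d["type"] = type(spec).__name__
    return d
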