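"""Core domain containers shared across the package.

Genotypes are diploid microsatellite calls (positive integer allele codes,
0 = missing).  Phenotypes live in a long-format :class:`pandas.DataFrame`
wrapped by :class:`PhenotypeTable`.  Symmetric population-pair matrices
(geographic km, pairwise theta) use :class:`PairwiseMatrix`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = 0  # allele code reserved for a missing gene copy

SEXES = ("M", "F", "unknown")

#: wavelength grid (nm) for reflectance spectra
WAVELENGTHS = np.arange(380, 740, 10)


class ValidationError(ValueError):
    """An input violated a domain-type invariant."""


@dataclass(frozen=True)
class Individual:
    id: str
    population: str
    region: str = ""
    sex: str = "unknown"

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")


@dataclass
class MicrosatDataset:
    """Diploid microsatellite calls for individuals grouped into populations.

    ``calls`` has shape (n_individuals, n_loci, 2); allele codes are strictly
    positive integers and 0 marks a missing gene copy.  A call with any
    missing copy is treated as missing for that individual x locus.
    """

    individuals: list[Individual]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, l = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, l, 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {l} loci x 2"
            )
        if (self.calls < 0).any():
            raise ValidationError("allele codes must be nonnegative (0 = missing)")
        # one population -> exactly one region
        reg = {}
        for ind in self.individuals:
            if ind.population in reg and reg[ind.population] != ind.region:
                raise ValidationError(
                    f"population {ind.population!r} maps to two regions "
                    f"({reg[ind.population]!r}, {ind.region!r})"
                )
            reg[ind.population] = ind.region
        self._region_of = reg

    # -- structure ---------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def populations(self) -> list[str]:
        """Population names in first-appearance order."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population, None)
        return list(seen)

    def region_of(self, population: str) -> str:
        return self._region_of[population]

    @property
    def regions(self) -> dict[str, list[str]]:
        """Mapping region -> populations (both in first-appearance order)."""
        out: dict[str, list[str]] = {}
        for pop in self.populations:
            out.setdefault(self.region_of(pop), []).append(pop)
        return out

    def indices_of(self, population: str) -> np.ndarray:
        return np.array(
            [i for i, ind in enumerate(self.individuals) if ind.population == population],
            dtype=int,
        )

    def subset(
        self,
        populations: Sequence[str] | None = None,
        sex: str | None = None,
        loci: Sequence[str] | None = None,
    ) -> "MicrosatDataset":
        keep = [
            i
            for i, ind in enumerate(self.individuals)
            if (populations is None or ind.population in set(populations))
            and (sex is None or ind.sex == sex)
        ]
        lkeep = (
            list(range(len(self.loci)))
            if loci is None
            else [self.loci.index(name) for name in loci]
        )
        return MicrosatDataset(
            [self.individuals[i] for i in keep],
            [self.loci[j] for j in lkeep],
            self.calls[np.ix_(keep, lkeep)],
        )

    def drop_loci(self, names: Iterable[str]) -> "MicrosatDataset":
        drop = set(names)
        keep = [name for name in self.loci if name not in drop]
        return self.subset(loci=keep)

    # -- allele bookkeeping ------------------------------------------------
    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    def genotypes(self, population: str, locus: str) -> np.ndarray:
        """Non-missing diploid calls (k, 2) for one population x locus."""
        j = self.locus_index(locus)
        g = self.calls[self.indices_of(population), j, :]
        return g[(g > 0).all(axis=1)]

    def allele_counts(self, population: str, locus: str) -> Counter:
        """Gene-copy counts of each allele among non-missing calls."""
        return Counter(self.genotypes(population, locus).ravel().tolist())


@dataclass
class PhenotypeTable:
    """Long-format trait table: one row per (individual, trait)."""

    REQUIRED = ["individual", "population", "region", "sex", "year", "trait", "value"]

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"phenotype table missing columns {missing}")
        dup = self.df.duplicated(subset=["individual", "trait"])
        if dup.any():
            raise ValidationError(
                f"duplicate (individual, trait) rows at index {list(self.df.index[dup])[:5]}"
            )
        vals = pd.to_numeric(self.df["value"], errors="coerce")
        if not np.isfinite(vals).all():
            bad = list(self.df.index[~np.isfinite(vals)])[:5]
            raise ValidationError(f"non-finite trait values at rows {bad}")
        self.df = self.df.assign(value=vals.astype(float))
        bright = self.df["trait"].astype(str).str.contains("brightness", case=False)
        out_of_range = bright & ~self.df["value"].between(0.0, 1.0)
        if out_of_range.any():
            raise ValidationError(
                f"brightness values outside [0, 1] at rows {list(self.df.index[out_of_range])[:5]}"
            )

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.df["trait"]))

    def trait_frame(self, trait: str) -> pd.DataFrame:
        return self.df[self.df["trait"] == trait].reset_index(drop=True)

    def restrict_to(self, individuals: Iterable[str]) -> "PhenotypeTable":
        keep = set(individuals)
        return PhenotypeTable(self.df[self.df["individual"].isin(keep)].reset_index(drop=True))


@dataclass
class LocalityTable:
    """Named capture sites with decimal-degree coordinates."""

    df: pd.DataFrame

    REQUIRED = ["name", "region", "latitude", "longitude"]

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"locality table missing columns {missing}")
        if self.df["name"].duplicated().any():
            raise ValidationError("locality names must be unique")
        lat = pd.to_numeric(self.df["latitude"], errors="raise")
        lon = pd.to_numeric(self.df["longitude"], errors="raise")
        if not lat.between(-90, 90).all():
            bad = list(self.df.loc[~lat.between(-90, 90), "name"])
            raise ValidationError(f"latitude outside [-90, 90] for {bad}")
        if not lon.between(-180, 180).all():
            bad = list(self.df.loc[~lon.between(-180, 180), "name"])
            raise ValidationError(f"longitude outside [-180, 180] for {bad}")
        self.df = self.df.assign(latitude=lat.astype(float), longitude=lon.astype(float))

    def coords(self, name: str) -> tuple[float, float]:
        row = self.df[self.df["name"] == name]
        if row.empty:
            raise KeyError(f"unknown locality {name!r}")
        return float(row["latitude"].iloc[0]), float(row["longitude"].iloc[0])


# -- behavioral assays -----------------------------------------------------

#: event kinds carrying no argument
SIMPLE_EVENTS = ("hop", "flight", "move", "enter_center", "leave_center")
#: event kinds carrying an integer id
ARG_EVENTS = ("enter_quarter", "land_perch")


@dataclass(frozen=True)
class AssayEvent:
    time: float  # minutes from assay start
    kind: str
    arg: int | None = None


@dataclass
class AssayLog:
    """Time-stamped event record of one open-field assay."""

    assay_id: str
    bird_id: str
    population: str
    duration: float  # minutes
    events: list[AssayEvent] = field(default_factory=list)
    n_quarters: int = 4
    n_perches: int = 6
    decorated_perches: frozenset = frozenset({1, 2, 3})

    def __post_init__(self):
        if self.duration <= 0:
            raise ValidationError("assay duration must be positive")
        self.decorated_perches = frozenset(self.decorated_perches)
        if not self.decorated_perches <= set(range(1, self.n_perches + 1)):
            raise ValidationError("decorated perch ids outside arena config")
        prev = 0.0
        for ev in self.events:
            if ev.kind not in SIMPLE_EVENTS + ARG_EVENTS:
                raise ValidationError(f"unknown event kind {ev.kind!r}")
            if ev.time < prev - 1e-12 or ev.time > self.duration + 1e-12:
                raise ValidationError(
                    f"event at t={ev.time} violates nondecreasing-within-duration"
                )
            prev = ev.time
            if ev.kind == "enter_quarter" and not 1 <= (ev.arg or 0) <= self.n_quarters:
                raise ValidationError(f"quarter id {ev.arg} outside arena config")
            if ev.kind == "land_perch" and not 1 <= (ev.arg or 0) <= self.n_perches:
                raise ValidationError(f"perch id {ev.arg} outside arena config")

    def count(self, kind: str) -> int:
        return sum(ev.kind == kind for ev in self.events)

    def distinct(self, kind: str) -> int:
        return len({ev.arg for ev in self.events if ev.kind == kind})


@dataclass
class SpectrumTable:
    """Reflectance spectra on the fixed 380-730 nm, 10 nm grid (36 points)."""

    samples: list[str]
    reflectance: np.ndarray  # (n_samples, 36)

    def __post_init__(self):
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 2 or self.reflectance.shape[1] != len(WAVELENGTHS):
            raise ValidationError(
                f"spectra must have exactly {len(WAVELENGTHS)} wavelength points "
                f"(380-730 nm at 10 nm); got shape {self.reflectance.shape}"
            )
        if self.reflectance.shape[0] != len(self.samples):
            raise ValidationError("sample names do not match spectrum rows")
        if (self.reflectance < 0).any():
            raise ValidationError("reflectance must be nonnegative")


@dataclass
class PairwiseMatrix:
    """Symmetric zero-diagonal matrix over a fixed population order."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValidationError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) values in row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def clip_negative(self) -> "PairwiseMatrix":
        """Return a copy with negative entries set to 0 (distance convention)."""
        return PairwiseMatrix(list(self.labels), np.maximum(self.values, 0.0))

    def reorder(self, labels: Sequence[str]) -> "PairwiseMatrix":
        idx = [self.labels.index(x) for x in labels]
        return PairwiseMatrix(list(labels), self.values[np.ix_(idx, idx)])
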