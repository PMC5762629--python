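"""Geographic distances and the Mantel test for isolation by distance."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import LocalityTable, PairwiseMatrix

EARTH_RADIUS_KM = 6371.0


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine great-circle distance on a sphere of radius 6371 km."""
    for lat in (lat1, lat2):
        if not -90 <= lat <= 90:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180 <= lon <= 180:
            raise ValueError(f"longitude {lon} outside [-180, 180]")
    phi1, phi2, la1, la2 = np.radians([lat1, lat2, lon1, lon2])
    h = np.sin((phi2 - phi1) / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(
        (la2 - la1) / 2
    ) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def distance_matrix(
    localities: LocalityTable, population_locality: dict[str, str]
) -> PairwiseMatrix:
    """Symmetric km matrix over populations.

    ``population_locality`` maps each population to its representative
    locality (for merged populations: the first-listed member by default,
    overridable).  Raises KeyError for an unmapped population or unknown
    locality.
    """
    pops = list(population_locality)
    coords = [localities.coords(population_locality[p]) for p in pops]
    n = len(pops)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = great_circle_km(*coords[i], *coords[j])
            values[i, j] = values[j, i] = d
    return PairwiseMatrix(pops, values)


@dataclass
class MantelResult:
    z: float  # sum of cross-products over unordered pairs
    r: float  # Pearson correlation over unordered pairs
    p: float  # one-tailed permutation p
    n_perm: int
    seed: int
    tail: str = "greater"


def mantel(
    x: PairwiseMatrix,
    y: PairwiseMatrix,
    n_perm: int = 10000,
    seed: int = 0,
    tail: str = "greater",
) -> MantelResult:
    """Mantel matrix-correlation test.

    Z is the sum of cross-products and r the Pearson correlation over the
    n(n-1)/2 unordered off-diagonal pairs.  p is the share of joint
    row/column permutations of ``y`` whose r is at least (``greater``) or at
    most (``less``) the observed one, with the identity permutation counted
    in numerator and denominator.
    """
    if x.labels != y.labels:
        raise ValueError("matrices must share labels and order")
    n = x.n
    if n < 3:
        raise ValueError("Mantel test needs at least 3 populations")
    iu = np.triu_indices(n, k=1)
    xv, yv = x.values[iu], y.values[iu]
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance in off-diagonal values; r undefined")
    z = float(np.sum(xv * yv))
    r_obs = float(np.corrcoef(xv, yv)[0, 1])

    rng = np.random.default_rng(seed)
    hits = 1  # identity permutation
    ym = y.values
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = np.corrcoef(xv, ym[np.ix_(perm, perm)][iu])[0, 1]
        if (tail == "greater" and r_perm >= r_obs - 1e-15) or (
            tail == "less" and r_perm <= r_obs + 1e-15
        ):
            hits += 1
    return MantelResult(z, r_obs, hits / (n_perm + 1), n_perm, seed, tail)
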