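import numpy as np
import pytest

from sparrowdiv.types import Individual, MicrosatDataset


def build_dataset(pop_genotypes: dict[str, list[list[tuple[int, int]]]],
                  loci: list[str] | None = None,
                  regions: dict[str, str] | None = None) -> MicrosatDataset:
    """Small-dataset builder: population -> per-individual list of allele
    pairs (one pair per locus; (0, 0) = missing)."""
    n_loci = len(next(iter(pop_genotypes.values()))[0])
    loci = loci or [f"L{j + 1}" for j in range(n_loci)]
    individuals, calls = [], []
    for pop, genos in pop_genotypes.items():
        for i, row in enumerate(genos):
            individuals.append(
                Individual(
                    id=f"{pop}_i{i + 1}",
                    population=pop,
                    region=(regions or {}).get(pop, ""),
                )
            )
            calls.append([tuple(sorted(pair)) for pair in row])
    return MicrosatDataset(individuals, loci, np.array(calls, dtype=np.int64))


@pytest.fixture
def two_pop_fixed():
    """Two populations fixed for different alleles at both loci."""
    return build_dataset(
        {
            "A": [[(1, 1), (5, 5)]] * 8,
            "B": [[(2, 2), (6, 6)]] * 8,
        }
    )


@pytest.fixture
def toy_three_pop():
    """Small polymorphic 3-population, 2-locus dataset (unequal sizes)."""
    rng = np.random.default_rng(42)
    pops = {}
    for name, n, freqs in [
        ("A", 6, [0.6, 0.3, 0.1]),
        ("B", 5, [0.2, 0.5, 0.3]),
        ("C", 7, [0.1, 0.2, 0.7]),
    ]:
        genos = []
        for _ in range(n):
            row = []
            for _locus in range(2):
                pair = tuple(sorted(rng.choice([1, 2, 3], size=2, p=freqs) ))
                row.append((int(pair[0]), int(pair[1])))
            genos.append(row)
        pops[name] = genos
    return build_dataset(pops)
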