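from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from sparrowdiv import synthgen
from sparrowdiv.popgen import (
    allelic_richness,
    fis,
    heterozygosity,
    hwe_test,
    null_allele_estimate,
    private_allelic_richness,
)
from sparrowdiv.popgen.diversity import diversity_summary, min_copies

from conftest import build_dataset


class TestHeterozygosity:
    def test_monomorphic_is_zero_zero(self):
        ds = build_dataset({"p": [[(1, 1)]] * 5})
        assert heterozygosity(ds, "p", "L1") == (0.0, 0.0)

    def test_two_heterozygotes_hand_value(self):
        """n=2, both {A,B}: H_O = 1, H_E = (4/3)(1 - 0.5) = 2/3."""
        ds = build_dataset({"p": [[(1, 2)], [(1, 2)]]})
        ho, he = heterozygosity(ds, "p", "L1")
        assert ho == 1.0
        assert he == pytest.approx(2 / 3)

    def test_all_missing_flagged_not_zero(self):
        ds = build_dataset({"p": [[(0, 0)]] * 3})
        ho, he = heterozygosity(ds, "p", "L1")
        assert np.isnan(ho) and np.isnan(he)

    def test_monte_carlo_unbiasedness(self):
        """The (2n/(2n-1)) correction makes H_E unbiased for the population
        gene diversity 1 - sum p^2 (Monte Carlo over repeated samples)."""
        p = np.array([0.5, 0.3, 0.2])
        n = 20
        rng = np.random.default_rng(0)
        hes = []
        for _ in range(300):
            geno = rng.choice(3, size=(n, 2), p=p) + 1
            ds = build_dataset({"p": [[tuple(sorted(g))] for g in geno.tolist()]})
            hes.append(heterozygosity(ds, "p", "L1")[1])
        assert np.mean(hes) == pytest.approx(1 - np.sum(p**2), abs=0.01)


class TestFis:
    def test_all_heterozygotes_negative(self):
        ds = build_dataset({"p": [[(1, 2)], [(1, 2)], [(1, 2)], [(1, 2)]]})
        assert fis(ds, "p").estimate < 0

    def test_fully_selfed_is_one(self):
        ds = build_dataset(
            {"p": [[(1, 1), (3, 3)], [(2, 2), (4, 4)], [(1, 1), (3, 3)],
                   [(2, 2), (4, 4)]]}
        )
        assert fis(ds, "p").estimate == pytest.approx(1.0)

    def test_hw_population_ci_covers_zero_mostly(self):
        """Random-mating truth F_IS = 0 sits inside the 95% CI in the large
        majority of replicates (the bootstrap over loci undercovers a
        little at a finite locus count, so the bound allows for that)."""
        hits = 0
        for seed in range(20):
            spec = synthgen.GenoSimSpec(
                n_pops=1, n_per_pop=40, n_loci=20, panmictic=True, seed=seed
            )
            ds = synthgen.simulate_genotypes(spec)
            res = fis(ds, ds.populations[0], seed=seed)
            if res.ci_low <= 0.0 <= res.ci_high:
                hits += 1
        assert hits >= 16

    def test_single_locus_degenerate_ci(self):
        ds = build_dataset({"p": [[(1, 2)], [(1, 1)], [(2, 2)]]})
        res = fis(ds, "p")
        assert res.ci_low == res.estimate == res.ci_high


class TestAllelicRichness:
    def test_g_equals_n_gives_observed_count(self):
        ds = build_dataset({"p": [[(1, 2)], [(1, 3)], [(3, 3)]]})
        assert allelic_richness(ds, "p", "L1", 6) == pytest.approx(3.0)

    def test_enumerated_toy_value(self):
        """4 copies, counts {2,2}, g=2: exhaustive over C(4,2)=6 subsamples
        gives (4*2 + 2*1)/6 = 5/3 distinct alleles on average."""
        ds = build_dataset({"p": [[(1, 1)], [(2, 2)]]})
        assert allelic_richness(ds, "p", "L1", 2) == pytest.approx(5 / 3)

    def test_matches_exhaustive_enumeration(self):
        """Direct enumeration oracle on a random 8-copy configuration."""
        ds = build_dataset({"p": [[(1, 2)], [(1, 1)], [(3, 2)], [(1, 3)]]})
        copies = [1, 2, 1, 1, 3, 2, 1, 3]
        for g in (2, 3, 5):
            exp = np.mean(
                [len(set(sub)) for sub in combinations(copies, g)]
            )
            assert allelic_richness(ds, "p", "L1", g) == pytest.approx(exp)

    def test_monotone_in_g(self):
        rng = np.random.default_rng(5)
        geno = rng.integers(1, 5, size=(10, 2))
        ds = build_dataset({"p": [[tuple(sorted(g))] for g in geno.tolist()]})
        values = [allelic_richness(ds, "p", "L1", g) for g in range(1, 21)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_bad_g_rejected(self):
        ds = build_dataset({"p": [[(1, 2)]] * 3})
        with pytest.raises(ValueError):
            allelic_richness(ds, "p", "L1", 0)
        with pytest.raises(ValueError):
            allelic_richness(ds, "p", "L1", 7)


class TestPrivateAllelicRichness:
    def test_disjoint_allele_sets_equal_ar(self):
        ds = build_dataset({"A": [[(1, 2)], [(2, 2)]], "B": [[(3, 4)], [(4, 4)]]})
        for pop in ("A", "B"):
            assert private_allelic_richness(ds, pop, "L1", 3) == pytest.approx(
                allelic_richness(ds, pop, "L1", 3)
            )

    def test_identical_populations_near_zero(self):
        geno = [[(1, 2)], [(1, 1)], [(2, 2)]]
        ds = build_dataset({"A": geno, "B": geno})
        assert private_allelic_richness(ds, "A", "L1", 6) < 0.05

    def test_brute_force_oracle_two_pops(self):
        """counts {A:3, B:1} vs {A:4}, g=2: average over all subsample pairs
        of the count of alleles in the focal sample absent from the other."""
        ds = build_dataset({"P1": [[(1, 1)], [(1, 2)]], "P2": [[(1, 1)], [(1, 1)]]})
        copies1, copies2 = [1, 1, 1, 2], [1, 1, 1, 1]
        vals = [
            len(set(s1) - set(s2))
            for s1 in combinations(copies1, 2)
            for s2 in combinations(copies2, 2)
        ]
        assert private_allelic_richness(ds, "P1", "L1", 2) == pytest.approx(
            np.mean(vals)
        )

    def test_sandwich_invariant(self):
        """0 <= A_PR(g) <= A_R(g) <= min(g, k_obs) on random fixtures."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            genos = {
                pop: [[tuple(sorted(rng.integers(1, 6, 2).tolist()))] for _ in range(6)]
                for pop in ("A", "B", "C")
            }
            ds = build_dataset(genos)
            g = min(min_copies(ds, "L1"), 8)
            for pop in ("A", "B", "C"):
                ar = allelic_richness(ds, pop, "L1", g)
                apr = private_allelic_richness(ds, pop, "L1", g)
                k_obs = len(ds.allele_counts(pop, "L1"))
                assert 0.0 <= apr <= ar + 1e-12 <= min(g, k_obs) + 1e-12


class TestHweTest:
    def test_hw_proportions_high_p(self):
        # 2 alleles at p=0.5, exact HW counts: 5 AA, 10 AB, 5 BB
        geno = [[(1, 1)]] * 5 + [[(1, 2)]] * 10 + [[(2, 2)]] * 5
        ds = build_dataset({"p": geno})
        assert hwe_test(ds, "p", "L1", n_perm=500, seed=1) > 0.5

    def test_all_heterozygotes_rejected(self):
        ds = build_dataset({"p": [[(1, 2)]] * 20})
        assert hwe_test(ds, "p", "L1", n_perm=2000, seed=2) < 0.01

    def test_monomorphic_p_one(self):
        ds = build_dataset({"p": [[(1, 1)]] * 10})
        assert hwe_test(ds, "p", "L1") == 1.0

    def test_calibration_under_hw(self):
        """p-values roughly uniform under random mating."""
        rng = np.random.default_rng(3)
        ps = []
        for seed in range(100):
            p = rng.dirichlet([2.0, 2.0, 2.0])
            geno = rng.choice(3, size=(20, 2), p=p) + 1
            ds = build_dataset({"p": [[tuple(sorted(g))] for g in geno.tolist()]})
            ps.append(hwe_test(ds, "p", "L1", n_perm=199, seed=seed))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestNullAlleles:
    def test_equal_heterozygosity_zero(self):
        # HW-proportioned: H_O ~ H_E, r near 0
        geno = [[(1, 1)]] * 5 + [[(1, 2)]] * 10 + [[(2, 2)]] * 5
        ds = build_dataset({"p": geno})
        assert abs(null_allele_estimate(ds, "p", "L1")) < 0.08

    def test_total_heterozygote_deficit_is_one(self):
        ds = build_dataset({"p": [[(1, 1)], [(2, 2)], [(1, 1)], [(2, 2)]]})
        assert null_allele_estimate(ds, "p", "L1") == pytest.approx(1.0)

    def test_moment_estimator_expectation(self):
        """True null frequency 0.2 under HW: E[r] ~ 0.2/1.2."""
        rng = np.random.default_rng(4)
        r_vals = []
        for _ in range(50):
            # visible alleles 1..4 at 0.2 each, null allele = 5 at 0.2
            geno = rng.choice(5, size=(100, 2), p=[0.2] * 5) + 1
            observed = []
            for a, b in geno:
                if a == 5 and b == 5:
                    continue  # null homozygote drops out (scored as missing)
                if a == 5:
                    a = b
                elif b == 5:
                    b = a
                observed.append(tuple(sorted((int(a), int(b)))))
            ds = build_dataset({"p": [[g] for g in observed]})
            r_vals.append(null_allele_estimate(ds, "p", "L1"))
        assert np.mean(r_vals) == pytest.approx(0.2 / 1.2, abs=0.07)


def test_diversity_summary_shape():
    spec = synthgen.GenoSimSpec(n_pops=3, n_per_pop=8, n_loci=4, F=0.02, seed=6)
    ds = synthgen.simulate_genotypes(spec)
    tab = diversity_summary(ds, seed=0)
    assert len(tab) == 3
    assert ((tab["H_E"] >= 0) & (tab["H_E"] <= 1)).all()
    assert ((tab["H_O"] >= 0) & (tab["H_O"] <= 1)).all()
    assert "bottleneck_p" not in tab.columns  # not requested
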