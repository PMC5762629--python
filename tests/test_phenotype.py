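import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sparrowdiv import synthgen
from sparrowdiv.phenotype import (
    compare_regions,
    exploration_score,
    latitude_regression,
    neophobia_score,
    spectrum_to_brightness,
)
from sparrowdiv.types import (
    AssayEvent,
    AssayLog,
    LocalityTable,
    PhenotypeTable,
    WAVELENGTHS,
)


class TestBrightness:
    def test_black_is_zero(self):
        assert spectrum_to_brightness(np.zeros(36)) == 0.0

    def test_perfect_reflector_is_white(self):
        assert spectrum_to_brightness(np.ones(36)) == pytest.approx(1.0, abs=1e-3)

    def test_grey_card_companding(self):
        """Flat 18% reflectance: green channel = sRGB companding of 0.18."""
        expected = 1.055 * 0.18 ** (1 / 2.4) - 0.055
        assert spectrum_to_brightness(np.full(36, 0.18)) == pytest.approx(
            expected, abs=1e-3
        )

    def test_monotone_in_uniform_scaling(self):
        levels = np.linspace(0.05, 0.95, 10)
        vals = [spectrum_to_brightness(np.full(36, lv)) for lv in levels]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_wrong_grid_rejected(self):
        with pytest.raises(ValueError):
            spectrum_to_brightness(np.ones(35))


def perch_log(bird, duration, n_perches, decorated=(1, 2, 3)):
    events = [
        AssayEvent(float(t), "land_perch", p + 1)
        for t, p in zip(np.linspace(0.5, duration - 0.5, n_perches), range(n_perches))
    ]
    return AssayLog(f"a_{bird}", bird, "p", duration, events,
                    decorated_perches=frozenset(decorated))


class TestExplorationScore:
    def test_worked_example_quarter_rate(self):
        """3 perches in 20 min against a best of 6 perches in 10 min -> 0.25."""
        best = perch_log("A", 10.0, 6)
        slow = perch_log("B", 20.0, 3)
        scores = exploration_score([best, slow]).set_index("bird")
        assert scores.loc["B", "perches"] == 0.25
        assert scores.loc["A", "perches"] == 1.0

    def test_zero_event_bird_scores_zero(self):
        active = perch_log("A", 10.0, 4)
        idle = AssayLog("a_B", "B", "p", 10.0, [])
        scores = exploration_score([active, idle]).set_index("bird")
        assert scores.loc["B", "exploration_total"] == 0.0

    def test_cohort_best_everywhere_totals_five(self):
        events = (
            [AssayEvent(0.5, "hop")] * 3
            + [AssayEvent(1.0, "flight")] * 2
            + [AssayEvent(2.0, "enter_quarter", q) for q in (1, 2, 3)]
            + [AssayEvent(5.0, "land_perch", p) for p in (1, 4)]
        )
        events.sort(key=lambda e: e.time)
        best = AssayLog("a_A", "A", "p", 10.0, events)
        other = perch_log("B", 20.0, 1)
        scores = exploration_score([best, other]).set_index("bird")
        assert scores.loc["A", "exploration_total"] == pytest.approx(5.0)

    def test_duration_rescaling_invariance(self):
        """Sub-scores depend on rates only: doubling every duration (with
        event counts fixed) leaves all sub-scores unchanged."""
        logs = [perch_log("A", 10.0, 6), perch_log("B", 20.0, 3)]
        doubled = [perch_log("A", 20.0, 6), perch_log("B", 40.0, 3)]
        a = exploration_score(logs).set_index("bird")
        b = exploration_score(doubled).set_index("bird")
        pd.testing.assert_frame_equal(a, b)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            exploration_score([])


class TestNeophobiaScore:
    def test_maximal_score(self):
        events = [AssayEvent(0.0, "enter_center"),
                  AssayEvent(5.0, "land_perch", 1)]
        log = AssayLog("a", "b", "p", 10.0, events)
        # center from 0 (never left; perch event doesn't end center time)
        ns = neophobia_score(log)
        assert ns.score == pytest.approx(1.0)

    def test_never_perched_never_center(self):
        log = AssayLog("a", "b", "p", 10.0, [AssayEvent(1.0, "hop")])
        ns = neophobia_score(log)
        assert ns.score == 0.0
        assert ns.never_perched

    def test_documented_combination_rule(self):
        """40% decorated perch share + 20% center share -> mean 0.30."""
        events = [
            AssayEvent(0.0, "enter_center"),
            AssayEvent(2.0, "leave_center"),
            AssayEvent(2.0, "land_perch", 1),   # decorated until t=5.2
            AssayEvent(5.2, "land_perch", 4),   # plain until assay end
        ]
        log = AssayLog("a", "b", "p", 10.0, events)
        ns = neophobia_score(log)
        assert ns.decorated_share == pytest.approx(0.4)
        assert ns.center_share == pytest.approx(0.2)
        assert ns.score == pytest.approx(0.30)
        assert neophobia_score(log, combine="sum").score == pytest.approx(0.60)


def region_table(values_by_region: dict[str, np.ndarray], trait="mass"):
    rows = []
    for region, vals in values_by_region.items():
        for i, v in enumerate(vals):
            rows.append(
                dict(individual=f"{region}_{i}", population=region, region=region,
                     sex="M", year=2015, trait=trait, value=float(v))
            )
    return PhenotypeTable(pd.DataFrame(rows))


class TestCompareRegions:
    def test_identical_regions_pairwise_p_one(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 30)
        phen = region_table({"R1": base, "R2": base.copy()})
        res = compare_regions(phen, "mass")
        assert res.p_raw > 0.9
        assert res.letters["R1"] == res.letters["R2"]

    def test_null_calibration(self):
        """Four regions from one distribution: rarely significant."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            phen = region_table({f"R{k}": rng.normal(0, 1, 20) for k in range(4)})
            res = compare_regions(phen, "mass", bonferroni_family=5)
            if res.p_adjusted <= 0.05:
                hits += 1
        assert hits <= 2

    def test_shifted_region_gets_unique_letter(self):
        rng = np.random.default_rng(3)
        phen = region_table(
            {"R1": rng.normal(0, 1, 25), "R2": rng.normal(0, 1, 25),
             "R3": rng.normal(5, 1, 25)}
        )
        res = compare_regions(phen, "mass")
        assert res.p_adjusted < 0.05
        letters = res.letters
        assert letters["R3"] not in (letters["R1"], letters["R2"])
        assert set(letters["R3"]).isdisjoint(set(letters["R1"]))

    def test_heteroscedastic_routes_to_welch(self):
        rng = np.random.default_rng(4)
        phen = region_table(
            {"R1": rng.normal(0, 0.3, 40), "R2": rng.normal(0, 3.0, 40),
             "R3": rng.lognormal(0, 1.0, 40)}
        )
        res = compare_regions(phen, "mass")
        assert res.test == "Welch+Kruskal-Wallis"
        assert res.kruskal_p is not None

    def test_letters_consistent_with_pairwise(self):
        """Sharing a letter <=> not significantly different."""
        rng = np.random.default_rng(5)
        phen = region_table(
            {"R1": rng.normal(0, 1, 30), "R2": rng.normal(1.2, 1, 30),
             "R3": rng.normal(2.4, 1, 30), "R4": rng.normal(10, 1, 30)}
        )
        res = compare_regions(phen, "mass")
        pair = res.pairwise_p
        for _, row in pair.iterrows():
            shared = set(res.letters[row["group1"]]) & set(res.letters[row["group2"]])
            significant = (
                bool(row["reject"]) if "reject" in row else row["p_adj"] < 0.05
            )
            assert significant == (len(shared) == 0)

    def test_small_region_rejected(self):
        phen = region_table({"R1": np.arange(5.0), "R2": np.array([1.0])})
        with pytest.raises(ValueError, match="< 2"):
            compare_regions(phen, "mass")


class TestLatitudeRegression:
    def _localities(self, pops, lats):
        df = pd.DataFrame(
            {"name": pops, "region": ["R"] * len(pops),
             "latitude": lats, "longitude": [35.0] * len(pops)}
        )
        return LocalityTable(df)

    def test_exact_linear_relation(self):
        pops = ["p1", "p2", "p3", "p4"]
        lats = [30.0, 31.0, 32.0, 33.0]
        rows = []
        for pop, lat in zip(pops, lats):
            for i in range(3):
                rows.append(dict(individual=f"{pop}_{i}", population=pop,
                                 region="R", sex="M", year=2015, trait="mass",
                                 value=2.0 * lat))
        phen = PhenotypeTable(pd.DataFrame(rows))
        res = latitude_regression(phen, "mass", self._localities(pops, lats),
                                  dict(zip(pops, pops)))
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_null_slope_ci_covers_zero(self):
        hits = 0
        pops = [f"p{k}" for k in range(6)]
        lats = np.linspace(30, 33, 6).tolist()
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rows = [
                dict(individual=f"{pop}_{i}", population=pop, region="R", sex="M",
                     year=2015, trait="mass", value=float(rng.normal()))
                for pop in pops
                for i in range(10)
            ]
            phen = PhenotypeTable(pd.DataFrame(rows))
            res = latitude_regression(phen, "mass", self._localities(pops, lats),
                                      dict(zip(pops, pops)))
            if res.slope_ci[0] <= 0.0 <= res.slope_ci[1]:
                hits += 1
        assert hits >= 8

    def test_recovers_body_size_gradient(self):
        """Synthetic latitudinal size cline: positive slope, significant."""
        spec = synthgen.PhenoSimSpec(
            n_pops=10, n_per_pop=15, sigma2_between=0.1, sigma2_within=1.0,
            latitude_slope=1.0, seed=2,
        )
        phen = synthgen.simulate_phenotypes(spec)
        pops = sorted(set(phen.df["population"]))
        lats = synthgen.population_latitudes(len(pops)).tolist()
        res = latitude_regression(phen, "trait", self._localities(pops, lats),
                                  dict(zip(pops, pops)))
        assert res.slope > 0
        assert res.p_value < 0.05

    def test_too_few_latitudes_rejected(self):
        pops = ["p1", "p2"]
        rows = [
            dict(individual=f"{p}_{i}", population=p, region="R", sex="M",
                 year=2015, trait="mass", value=float(i))
            for p in pops
            for i in range(3)
        ]
        phen = PhenotypeTable(pd.DataFrame(rows))
        with pytest.raises(ValueError, match="latitudes"):
            latitude_regression(phen, "mass", self._localities(pops, [30.0, 31.0]),
                                dict(zip(pops, pops)))
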