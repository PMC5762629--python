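"""Raw measurements to analysis-ready traits, and the region/latitude
comparisons.

Covers the spectral-reflectance -> brightness conversion (D65 illuminant,
CIE 1931 2-degree observer, sRGB green channel on a 0-1 scale), behavioral
scoring of open-field assays (exploration sub-scores normalized by assay
duration and relative to the cohort best; neophobia from decorated-perch
use and center occupancy), assumption-guided region comparisons (ANOVA +
Tukey, or Welch + Kruskal-Wallis + Dunn), and latitude regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.oneway import anova_oneway
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from ._cie import CIE_1931_2DEG, D65, XYZ_TO_SRGB, srgb_companding
from .types import AssayLog, LocalityTable, PhenotypeTable, SpectrumTable, WAVELENGTHS


# ---------------------------------------------------------------------------
# Color brightness
# ---------------------------------------------------------------------------

def spectrum_to_brightness(reflectance: np.ndarray) -> float:
    """Brightness of a reflectance spectrum as the sRGB green channel in [0, 1].

    reflectance x D65 -> CIE 1931 2-degree XYZ (normalized so a perfect
    reflector has Y = 1) -> linear sRGB -> gamma companding -> clip.
    0 = black, 1 = white.
    """
    r = np.asarray(reflectance, dtype=float)
    if r.shape != (len(WAVELENGTHS),):
        raise ValueError(
            f"spectrum must sample 380-730 nm at 10 nm ({len(WAVELENGTHS)} points)"
        )
    k = 1.0 / np.sum(D65 * CIE_1931_2DEG[:, 1])
    xyz = k * (D65[:, None] * CIE_1931_2DEG * r[:, None]).sum(axis=0)
    rgb_lin = np.clip(XYZ_TO_SRGB @ xyz, 0.0, 1.0)
    return float(np.clip(srgb_companding(rgb_lin), 0.0, 1.0)[1])


def brightness_table(table: SpectrumTable) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": table.samples,
            "brightness": [spectrum_to_brightness(row) for row in table.reflectance],
        }
    )


# ---------------------------------------------------------------------------
# Behavioral scoring
# ---------------------------------------------------------------------------

#: the five exploration variables
EXPLORATION_VARS = ("quarters", "perches", "location_changes", "hops", "flights")

#: event kinds counted as a location change (quarter/perch transitions)
LOCATION_CHANGE_KINDS = ("move", "enter_quarter", "land_perch")


def _raw_exploration(log: AssayLog) -> dict[str, float]:
    return dict(
        quarters=min(log.distinct("enter_quarter"), log.n_quarters),
        perches=min(log.distinct("land_perch"), log.n_perches),
        location_changes=sum(log.count(k) for k in LOCATION_CHANGE_KINDS),
        hops=log.count("hop"),
        flights=log.count("flight"),
    )


def exploration_score(logs: list[AssayLog]) -> pd.DataFrame:
    """Duration-normalized, cohort-relative exploration scores.

    Each variable becomes a rate (count / duration); the sub-score is that
    rate divided by the best rate in the cohort (0 when the cohort best is
    0), so every sub-score lies in [0, 1] and the total in [0, 5].
    """
    if not logs:
        raise ValueError("empty cohort")
    rates = pd.DataFrame(
        [
            {**{k: v / log.duration for k, v in _raw_exploration(log).items()},
             "bird": log.bird_id, "population": log.population}
            for log in logs
        ]
    )
    best = rates[list(EXPLORATION_VARS)].max(axis=0)
    out = rates[["bird", "population"]].copy()
    for var in EXPLORATION_VARS:
        out[var] = 0.0 if best[var] == 0 else rates[var] / best[var]
    out["exploration_total"] = out[list(EXPLORATION_VARS)].sum(axis=1)
    return out


@dataclass
class NeophobiaScore:
    bird: str
    score: float
    decorated_share: float
    center_share: float
    never_perched: bool


def _perched_intervals(log: AssayLog) -> list[tuple[float, float, bool]]:
    """(start, end, decorated) perch occupancy: a landing lasts until the
    next event of any kind, or the end of the assay."""
    out = []
    for idx, ev in enumerate(log.events):
        if ev.kind != "land_perch":
            continue
        end = log.events[idx + 1].time if idx + 1 < len(log.events) else log.duration
        out.append((ev.time, end, ev.arg in log.decorated_perches))
    return out


def neophobia_score(log: AssayLog, combine: str = "mean") -> NeophobiaScore:
    """Neophobia score in [0, 1]; higher = reduced neophobic response.

    Combines the share of perched time spent on decorated perches and the
    share of the assay spent in the center of the arena (``combine`` is
    "mean" or "sum"; a sum is rescaled by 1/2 to stay in [0, 1]).  A bird
    that never perched contributes 0 for the decorated share, flagged.
    """
    perched = _perched_intervals(log)
    total_perched = sum(e - s for s, e, _ in perched)
    decorated = sum(e - s for s, e, d in perched if d)
    decorated_share = decorated / total_perched if total_perched > 0 else 0.0

    center = 0.0
    entered: float | None = None
    for ev in log.events:
        if ev.kind == "enter_center" and entered is None:
            entered = ev.time
        elif ev.kind == "leave_center" and entered is not None:
            center += ev.time - entered
            entered = None
    if entered is not None:
        center += log.duration - entered
    center_share = center / log.duration

    if combine not in ("mean", "sum"):
        raise ValueError("combine must be 'mean' or 'sum'")
    score = (decorated_share + center_share) / 2.0
    if combine == "sum":
        score = decorated_share + center_share  # in [0, 2]
    return NeophobiaScore(
        bird=log.bird_id,
        score=float(score),
        decorated_share=float(decorated_share),
        center_share=float(center_share),
        never_perched=total_perched == 0,
    )


# ---------------------------------------------------------------------------
# Region comparisons
# ---------------------------------------------------------------------------

@dataclass
class RegionComparison:
    trait: str
    test: str  # ANOVA | Welch+Kruskal-Wallis
    statistic: float
    df: tuple
    p_raw: float
    p_adjusted: float
    normality_p: float
    homoscedasticity_p: float
    letters: dict[str, str] = field(default_factory=dict)
    pairwise_p: pd.DataFrame | None = None
    kruskal_statistic: float | None = None
    kruskal_p: float | None = None


def _compact_letters(groups: list[str], sig: dict[frozenset, bool]) -> dict[str, str]:
    """Insert-and-absorb compact letter display from a pairwise
    significance map (True = significantly different)."""
    letters: list[set[str]] = [set(groups)]
    for a, b in combinations(groups, 2):
        if not sig.get(frozenset((a, b)), False):
            continue
        for col in list(letters):
            if a in col and b in col:
                letters.remove(col)
                ca, cb = col - {b}, col - {a}
                for c in (ca, cb):
                    if not any(c <= other for other in letters):
                        letters.append(c)
    letters.sort(key=lambda col: sorted(groups.index(g) for g in col))
    out = {g: "" for g in groups}
    for i, col in enumerate(letters):
        for g in col:
            out[g] += chr(ord("a") + i)
    return {g: "".join(sorted(v)) for g, v in out.items()}


def _dunn_pairwise(values: list[np.ndarray], names: list[str]) -> pd.DataFrame:
    """Dunn's post-hoc z-tests on mean ranks with tie correction,
    Bonferroni-adjusted across the group pairs."""
    all_vals = np.concatenate(values)
    ranks = stats.rankdata(all_vals)
    n = len(all_vals)
    sizes = [len(v) for v in values]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(values))]
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12 * (n - 1))
    m = len(list(combinations(names, 2)))
    rows = []
    for (i, a), (j, b) in combinations(enumerate(names), 2):
        se = np.sqrt((n * (n + 1) / 12 - tie_term) * (1 / sizes[i] + 1 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2 * stats.norm.sf(abs(z))
        rows.append(dict(group1=a, group2=b, z=z, p_raw=p, p_adj=min(1.0, p * m)))
    return pd.DataFrame(rows)


def compare_regions(
    phenotypes: PhenotypeTable,
    trait: str,
    alpha: float = 0.05,
    bonferroni_family: int = 1,
) -> RegionComparison:
    """Compare a trait across regions with an assumption-guided test choice.

    Shapiro-Wilk on the one-way model residuals and Levene's test decide the
    route: ANOVA + Tukey when both pass at ``alpha``, otherwise Welch's
    ANOVA plus Kruskal-Wallis with Dunn's post-hoc.  ``bonferroni_family``
    scales the reported adjusted p (the number of traits analyzed in one
    run).  Pairwise results are summarized as a compact letter display.
    """
    df = phenotypes.trait_frame(trait)
    counts = df.groupby("region")["value"].count()
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise ValueError(f"regions with < 2 observations: {small}")
    regions = list(dict.fromkeys(df["region"]))
    values = [df.loc[df["region"] == r, "value"].to_numpy() for r in regions]

    resid = np.concatenate([v - v.mean() for v in values])
    norm_p = float(stats.shapiro(resid).pvalue) if 3 <= len(resid) <= 5000 else float(
        stats.normaltest(resid).pvalue
    )
    lev_p = float(stats.levene(*values).pvalue)

    if norm_p > alpha and lev_p > alpha:
        f_stat, p_raw = stats.f_oneway(*values)
        if not np.isfinite(p_raw):  # degenerate F (identical groups)
            f_stat, p_raw = max(float(f_stat), 0.0), 1.0
        dfs = (len(regions) - 1, len(resid) - len(regions))
        tuk = pairwise_tukeyhsd(df["value"], df["region"], alpha=alpha)
        pair_df = pd.DataFrame(
            tuk.summary().data[1:], columns=tuk.summary().data[0]
        ).rename(columns={"p-adj": "p_adj"})
        sig = {
            frozenset((row["group1"], row["group2"])): bool(row["reject"])
            for _, row in pair_df.iterrows()
        }
        result = RegionComparison(
            trait=trait, test="ANOVA", statistic=float(f_stat), df=dfs,
            p_raw=float(p_raw), p_adjusted=min(1.0, float(p_raw) * bonferroni_family),
            normality_p=norm_p, homoscedasticity_p=lev_p,
            letters=_compact_letters(regions, sig), pairwise_p=pair_df,
        )
    else:
        welch = anova_oneway(df["value"], df["region"], use_var="unequal",
                             welch_correction=True)
        kw_stat, kw_p = stats.kruskal(*values)
        dunn = _dunn_pairwise(values, regions)
        sig = {
            frozenset((row["group1"], row["group2"])): row["p_adj"] < alpha
            for _, row in dunn.iterrows()
        }
        result = RegionComparison(
            trait=trait, test="Welch+Kruskal-Wallis", statistic=float(welch.statistic),
            df=(float(welch.df_num), float(welch.df_denom)),
            p_raw=float(welch.pvalue),
            p_adjusted=min(1.0, float(welch.pvalue) * bonferroni_family),
            normality_p=norm_p, homoscedasticity_p=lev_p,
            letters=_compact_letters(regions, sig), pairwise_p=dunn,
            kruskal_statistic=float(kw_stat), kruskal_p=float(kw_p),
        )
    return result


@dataclass
class RegressionResult:
    trait: str
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    slope_ci: tuple[float, float]
    sqrt_transformed: bool
    n: int


def latitude_regression(
    phenotypes: PhenotypeTable,
    trait: str,
    localities: LocalityTable,
    population_locality: dict[str, str],
    sqrt_transform: bool = False,
) -> RegressionResult:
    """OLS of the (optionally square-root-transformed) trait on latitude."""
    df = phenotypes.trait_frame(trait)
    lat = {
        pop: localities.coords(loc)[0] for pop, loc in population_locality.items()
    }
    df = df[df["population"].isin(lat)]
    x = df["population"].map(lat).to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct latitudes")
    y = df["value"].to_numpy(dtype=float)
    if sqrt_transform:
        if (y < 0).any():
            raise ValueError("square-root transform needs nonnegative values")
        y = np.sqrt(y)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int()[1]
    return RegressionResult(
        trait=trait,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        p_value=float(model.f_pvalue),
        slope_ci=(float(ci[0]), float(ci[1])),
        sqrt_transformed=sqrt_transform,
        n=int(model.nobs),
    )
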