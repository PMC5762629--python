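#!/usr/bin/env python
"""Trait construction and the region / latitude comparisons.

Converts the synthetic reflectance spectra to 0-1 brightness (D65, CIE 1931
2-degree observer, sRGB green channel), scores the open-field assays for
exploration (five duration-normalized, cohort-relative sub-scores summed to
0-5) and neophobia (decorated-perch use and center occupancy), then runs
the assumption-guided region comparisons and the latitude regressions on
the phenotype table.  The body-mass trait was generated with a positive
south-to-north slope (a body-size cline), the brightness trait with a
negative one (darker northward), so the regressions should recover those
signs.
"""

from pathlib import Path

import pandas as pd

from sparrowdiv import io_formats, phenotype

BUNDLE = Path("results/synthetic")
OUT = Path("results")


def main() -> None:
    spectra = io_formats.read_table(BUNDLE / "spectra.csv", "spectrum")
    bright = phenotype.brightness_table(spectra)
    bright.to_csv(OUT / "spectra_brightness.tsv", sep="\t", index=False)
    print(f"brightness of {len(bright)} spectra: "
          f"{bright['brightness'].min():.3f}-{bright['brightness'].max():.3f}")

    logs = io_formats.read_table(BUNDLE / "assays.csv", "assay")
    expl = phenotype.exploration_score(logs)
    neo = pd.DataFrame([vars(phenotype.neophobia_score(l)) for l in logs])
    expl.to_csv(OUT / "exploration_scores.tsv", sep="\t", index=False)
    neo.to_csv(OUT / "neophobia_scores.tsv", sep="\t", index=False)
    print(f"exploration totals (0-5): mean {expl['exploration_total'].mean():.2f}; "
          f"neophobia scores (0-1): mean {neo['score'].mean():.2f}")

    phen = io_formats.read_table(BUNDLE / "phenotypes.csv", "phenotype")
    localities = io_formats.read_table(BUNDLE / "localities.csv", "locality")
    pop_loc = {n: n for n in localities.df["name"]}

    rows = []
    for trait in phen.traits:
        cmp_res = phenotype.compare_regions(
            phen, trait, bonferroni_family=len(phen.traits)
        )
        reg = phenotype.latitude_regression(phen, trait, localities, pop_loc)
        rows.append(
            dict(trait=trait, test=cmp_res.test, statistic=cmp_res.statistic,
                 p_adjusted=cmp_res.p_adjusted,
                 letters=";".join(f"{k}={v}" for k, v in cmp_res.letters.items()),
                 slope=reg.slope, r_squared=reg.r_squared, slope_p=reg.p_value)
        )
        print(f"{trait}: {cmp_res.test} p_adj={cmp_res.p_adjusted:.3g}, "
              f"latitude slope {reg.slope:+.3f} (r2={reg.r_squared:.3f}, "
              f"p={reg.p_value:.2g})")
    pd.DataFrame(rows).to_csv(OUT / "region_and_latitude.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
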