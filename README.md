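# sparrowdiv

Phenotypic divergence versus neutral genetic differentiation (P_ST – F_ST)
for structured wild populations, built around a microsatellite survey of
house sparrows (*Passer domesticus*) sampled south to north across Israel's
steep climatic gradient.

The package is for population and evolutionary biologists who ask the
classic question: is the phenotypic variation among populations larger than
genetic drift alone can explain?  Common-garden Q_ST is rarely available
for wild birds, so the phenotypic proxy

    P_ST = (c/h² · σ²B) / (c/h² · σ²B + 2 σ²W)

is compared with the neutral baseline F_ST, where σ²B and σ²W are the
between- and within-population phenotypic variances, h² is narrow-sense
heritability and c the proportion of between-population variance that is
additive.  At c = h² the comparison is the standard one; the **critical
c/h²** — the ratio at which the lower 95% bound of P_ST meets the upper
95% bound of F_ST, `φ* = [F/(1−F)]·[(1−P_low)/P_low]` — measures how robust
a divergence verdict is to that untestable assumption (smaller = more
robust).

## What is implemented

- **io_formats** — GenePop (2/3-digit diploid microsatellites), phenotype /
  locality / assay-log / reflectance-spectrum CSVs, labeled symmetric
  matrices as TSV.
- **popgen** — unbiased expected heterozygosity, multilocus F_IS with
  bootstrap CI, Weir & Cockerham's θ (multilocus ratio-of-sums, bootstrap
  CI over loci, pairwise matrix with permutation p-values), hierarchical
  AMOVA, exact rarefied allelic and private allelic richness, Monte Carlo
  Hardy–Weinberg exact tests, the Chakraborty null-allele estimator, and
  the bottleneck heterozygosity-excess test with a coalescent simulator
  under IAM / SMM / TPM mutation models plus the mode-shift indicator.
- **spatial** — great-circle distances and the Mantel matrix-permutation
  test for isolation by distance.
- **phenotype** — reflectance → brightness (D65 illuminant, CIE 1931 2°
  observer, sRGB green channel on 0–1), open-field exploration and
  neophobia scoring, assumption-guided region comparisons (ANOVA + Tukey or
  Welch + Kruskal–Wallis + Dunn, compact letter displays), latitude
  regressions.
- **pstfst** — Gibbs sampler for the Gaussian random-intercept model,
  P_ST posteriors, critical c/h² (closed form and posterior-grid), and the
  ≫ / > / = verdict rule.
- **synthgen** — seeded generators with known ground truth for all of the
  above (Balding–Nichols island model, stepping-stone chain, Ewens-urn
  equilibrium populations, phenotype, assay and spectrum simulators).
- **pipeline / cli** — end-to-end orchestration from a YAML config
  (`sparrowdiv pipeline run --config run.yaml`) and per-stage subcommands.

The survey's printed summary tables (pairwise km and θ between the 14
genetic populations, the 18 locality coordinates, the published P_ST–F_ST
decision table) ship as package data in `sparrowdiv.study`.

## Worked example

The numbered scripts under `analysis/` replay the whole study design on a
synthetic replica (14 populations × 20 diploid individuals, 8 loci, island
model at F = 0.008).  Running them in order prints, among other things:

```
$ python analysis/01_simulate_study_bundle.py
ground truth: F_ST = 0.008, true body-mass P_ST = 0.167

$ python analysis/03_differentiation_and_ibd.py
multilocus theta = 0.0068 (95% CI [0.0018, 0.0117]; truth 0.008)
AMOVA: 99.33% of variance within populations
isolation by distance, published matrices:
  Mantel Z = 145.3, r = 0.37, p = 0.0045

$ python analysis/05_pst_fst.py
body_mass: P_ST = 0.169 [0.080, 0.346], critical c/h2 = 0.136, P_ST > F_ST
8/8 verdicts match the published labels
```

Reading: the θ estimator recovers the simulated differentiation; nearly all
genetic variance sits within populations (low structure, high gene flow);
the published distance/θ matrices yield the survey's isolation-by-distance
signal (r = 0.37); and the Bayesian P_ST machinery recovers the simulated
truth 0.167 and, applied to the published credible bounds, reproduces every
printed ≫ / > / = verdict.

A quick library-level call:

```python
from sparrowdiv import study, spatial
geo = study.geographic_km()
fst = study.pairwise_fst().clip_negative()   # θ as a nonnegative distance
print(spatial.mantel(geo, fst, n_perm=9999, seed=1))
# MantelResult(z=145.26..., r=0.3669..., p=0.0045..., ...)
```

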