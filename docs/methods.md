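# Methods

This note records the statistical models, the estimators, the synthetic
data the tests rely on, and the numerical and design choices that were
genuinely open.

## The P_ST – F_ST framework

Phenotypic differentiation is measured as

    P_ST(φ) = φ σ²B / (φ σ²B + 2 σ²W),      φ = c/h²,

with σ²B the between-population and σ²W the within-population (residual)
variance of a trait and φ the ratio of the additive proportion of
between-population variance (c) to narrow-sense heritability (h²).  P_ST
is evaluated per posterior draw of (σ²B, σ²W), so its point estimate
(posterior median at φ = 1; the median was chosen over mean/mode because it
commutes with the monotone map x ↦ x/(x+1) — configurable) and 95% credible
interval come for free.  A trait diverges detectably when the P_ST lower
bound exceeds the F_ST upper bound; the **critical ratio**

    φ* = [F/(1−F)] · [(1−P_low)/P_low]

is the exact inversion of P_ST(φ) at the lower bound, and satisfies
P_ST(φ*, ρ_low) = F to machine precision (property-tested).  A second,
posterior-grid mode recomputes the 2.5% quantile of P_ST on a φ grid and
bisects; on well-behaved posteriors the two agree to ~1% but they answer
slightly different questions (fixed plug-in bound vs. requantified bound),
which is why both are reported.  Verdicts: "=" when the bounds overlap,
">" otherwise, upgraded to "≫" when φ* ≤ 0.125.  The threshold is not part
of the published rule (the source table prints only the labels); 0.125 is
the value that separates the printed ≫ rows (φ* ≤ 0.124) from the printed
> rows (φ* ≥ 0.131), and it is exposed in the config.

### Variance components

σ²B and σ²W come from a Gaussian random-intercept model
y = Xβ + u_pop + e, u ~ N(0, σ²B), e ~ N(0, σ²W), fit by a conjugate Gibbs
sampler: flat β, inverse-gamma(ν/2, νV/2) on both variances with V = 1,
ν = 0.002 (the weakly-informative default of the reference mixed-model
package this reproduces).  Chain defaults 65 000 iterations, 15 000
burn-in, thinning 50 → 1 000 retained draws; sex enters as a fixed effect
for morphological traits and sampling year for color traits.  Effective
sample size and split-chain R̂ (via arviz; a single chain is split in
halves) are attached to every fit and the result is flagged when R̂ > 1.1.
On balanced designs the posterior medians track the one-way ANOVA
method-of-moments components (tested); with σ²B = 0 the posterior mass of
σ²B collapses below 0.1·σ²W.

## Genetic estimators

**Weir–Cockerham θ.**  Per-allele variance components a (among
populations), b (among individuals within), c (within individuals) with the
unequal-sample-size moment corrections; the multilocus estimate is the
ratio of summed components over loci and alleles — never the mean of
per-locus ratios (asserted on fixtures where the two differ).  Negative
estimates are reported as computed.  The 95% CI bootstraps loci; pairwise
significance permutes individuals between the two populations (10 000
default, seeded).  A second, loop-wise transcription of the formulas lives
in the test suite and must agree to 1e-12 on small datasets.

**F_IS.**  Single-population reduction of the same components,
f = 1 − Σc/Σ(b+c), bootstrap CI over loci.  The bootstrap-over-loci CI
undercovers slightly when few loci are available (it is a percentile
bootstrap with the locus as resampling unit); the coverage test therefore
runs at 20 loci.

**AMOVA.**  Classic gene-copy sums of squares with the 0/1 allele-identity
distance, three nested levels (region / population / within), unequal-size
coefficients, components summed across loci and percentages taken from the
summed components.  Negative components are reported.  Permutation tests:
individuals within regions (Φ_SC), individuals overall (Φ_ST), whole
populations across regions (Φ_CT).  The gene-copy decomposition omits the
within-individual correlation term that W-C θ carries, so Φ_ST ≈ θ rather
than identically equal (tolerance-tested at 0.02).

**Rarefaction.**  A_R(g) by exact hypergeometric combinatorics in log
space; private allelic richness by the product-of-absence form
Σ_i Q_ij(g) Π_{k≠j} (1 − Q_ik(g)).  Both are verified against exhaustive
enumeration of subsamples on small fixtures, and obey
0 ≤ A_PR ≤ A_R ≤ min(g, k) everywhere (property-tested).  The default g is
the smallest per-locus copy count across populations.

**Hardy–Weinberg.**  Monte Carlo exact test with Levene's conditional
probability as the ordering statistic (gene copies shuffled, p = share of
arrays no more probable than observed, add-one-in both numerator and
denominator).  Calibration is checked by a KS test of p-value uniformity
under random mating.

**Null alleles.**  Chakraborty's moment estimator r = (H_E−H_O)/(H_E+H_O);
the screening rule excludes a locus when its mean r across populations
exceeds 0.15 (configurable) or any population deviates from HW after
Bonferroni correction across the population × locus family.

**Bottleneck test.**  For each polymorphic locus, the equilibrium
distribution of expected heterozygosity conditional on the observed allele
count k is simulated by running the coalescent of the sampled gene copies
top-down (interval durations Exp(j(j−1)/2), one uniformly chosen lineage
splitting per interval) with Poisson(θ/2 per unit length) mutations under
IAM, SMM, or TPM (single-step with probability p_ss = 0.9, else a
geometric multi-step jump with variance 12 — common defaults for the
two-phase model, config-exposed).  θ is centred on the Ewens moment
estimate and the simulation rejects genealogies whose allele count differs
from k, cycling over a 12-point log-spaced θ grid skewed upward to absorb
size homoplasy under SMM/TPM.  The simulator reproduces the exact
Ewens-sampling-formula conditional heterozygosity at n = 6 (enumeration
oracle) and the H_eq ordering IAM < TPM < SMM at fixed (k, n).

The population-level signed-rank step needs care: H_eq | k is left-skewed,
so the raw excess H_E,obs − mean(H_eq) has a positive median *at
equilibrium* and a one-tailed Wilcoxon on it rejects 8–12% at nominal 5%
(measured here across θ 2–8, 8 loci).  The test therefore ranks each
locus's observed H_E within its own simulated null (mid-rank convention)
and applies the one-tailed Wilcoxon to rank − 1/2, which is symmetric at
equilibrium and keeps the step exact; the raw excess is still reported per
locus.  Measured type-I error: ≤ 7.5% over 200 equilibrium populations, at
the discrete signed-rank's achievable level (~3.9% for 8 loci).  The
mode-shift indicator bins all allele frequencies of a population into ten
right-inclusive classes of width 0.1 and flags when the rarest class
(0, 0.1] is not modal.

## Spatial analyses

Great-circle distances use the haversine formula on a sphere of radius
6371.0 km (the survey's web calculator is unspecified; the published
pairwise km reproduce within 0.31% for unmerged populations and the test
tolerance is 0.5%).  Merged populations use the first-listed locality of
the merge as representative (matches the published matrix within rounding;
overridable).  The Mantel statistic sums cross-products over unordered
pairs, r is the Pearson correlation over the same pairs, and p is the
share of joint row/column permutations (identity included) with r at least
the observed, one-tailed positive for isolation by distance.  **Negative
pairwise θ estimates are set to zero before the Mantel run** — a
differentiation *distance* cannot be negative, and this convention is what
reproduces the published Z = 145.3, r = 0.37 exactly from the printed
matrices (without it: Z = 140.5, r = 0.344).

## Trait construction

**Brightness.**  Reflectance (380–730 nm, 10 nm) × D65 → CIE 1931 2° XYZ
normalized so the perfect reflector has Y = 1 → linear sRGB via the
standard matrix → sRGB gamma → clip to [0, 1] → green channel.  The
pipeline's constants are pinned in `_cie.py` because the original
spectrophotometer software's settings are unstated; a flat 18% grey maps
to 0.4613 (closed-form gamma check) and brightness is monotone in uniform
reflectance scaling.

**Exploration.**  Five variables (distinct quarters ≤ 4, distinct perches
≤ 6, location changes = quarter/perch transitions, hops, flights), each
turned into a rate per minute and divided by the cohort-best rate, so
sub-scores lie in [0, 1] and the total in [0, 5].  Counting visited
entities rather than visit events follows the protocol's "number of
quarters visited (0 to 4)".

**Neophobia.**  Unweighted mean (configurable: sum) of the decorated-perch
share of perched time (perched from a landing until the next event or the
assay end; 0 with a flag when the bird never perched) and the center share
of assay time.  Higher = reduced neophobia.  Whether the original analysis
summed or averaged the two proportions is not stated; the mean keeps the
score in [0, 1].

**Region comparisons.**  Shapiro–Wilk on the one-way residuals and
Levene's test at α = 0.05 route each trait to ANOVA + Tukey or to Welch's
ANOVA + Kruskal–Wallis + Dunn (Dunn implemented in-package: z-tests on
mean ranks with tie correction, Bonferroni over pairs).  Bonferroni family
for the headline p = the set of traits analyzed in one run.  Compact
letter displays are built by insert-and-absorb and are checked for
consistency with the pairwise significance matrix.

## Synthetic data: what it emulates, what it does not

The generators define the study conditions for every recovery test:

- **Genotypes**: Balding–Nichols island model (population frequencies
  Dirichlet(p̄(1−F)/F) around ancestral p̄), so Wright's F is an explicit
  parameter; defaults 14 populations × 20 diploid individuals, 8 loci,
  4–28 alleles per locus, F = 0.008.  Ancestral spectra use a symmetric
  Dirichlet with concentration 0.3, which yields the skewed rare-allele
  spectra of real microsatellite surveys and expected heterozygosity in
  the mid-0.70s, matching the study regime.  The stepping-stone variant
  drifts frequencies along the population line with per-step variance
  δp(1−p) (Dirichlet kernel, clipped away from the absorbing boundaries —
  an approximation) and produces isolation by distance by construction.
  A separate Ewens-urn generator draws true mutation-drift-equilibrium
  samples for the bottleneck calibration, deliberately independent of the
  coalescent simulator inside the test.
- **Phenotypes**: grand mean + N(0, σ²B) population intercepts + optional
  latitudinal trend + sex/year effects + N(0, σ²W) residuals; the plug-in
  truth P_ST = φσ²B/(φσ²B + 2σ²W) anchors the recovery tests.
- **Assays**: homogeneous Poisson event streams; decorated-perch choice
  Bernoulli(neophobia bias); one contiguous center block.
- **Spectra**: flat reflectance at levels along a gradient, Gaussian
  noise, clipped at 0.

None of these emulate linkage, null alleles, genotyping error, allele-size
constraints, temporal sampling structure, or behavioral time-dependence;
passing recovery tests therefore demonstrates estimator correctness under
the stated models, not robustness to those real-data complications.  The
island-model frequency sampler is not a coalescent, so the bottleneck
column in the synthetic diversity table is demonstrative only.

## Problem sizes and numerical choices

Test and analysis problem sizes were chosen to make the checks sharp while
keeping the whole suite around a minute: θ recovery uses 20 seeds of
10 × 30 × 50 loci at F = 0.10; the P_ST recovery uses 20 seeds of 14 × 20
with 26 000-iteration chains (1 000 retained draws); bottleneck
calibration uses 200 equilibrium populations of 8 loci × 15 individuals
with 150 retained simulations per locus; pipeline smoke tests use reduced
permutation counts.  Seeds are fixed everywhere; hypothesis tests use
bounded example counts.  Percentile CIs are 2.5/97.5 throughout;
permutation p-values use the add-the-identity convention so p ∈ (0, 1];
ties in the mode-shift binning are right-inclusive; log-gamma is used for
all binomial coefficients.

## Known limitations

- GenePop files carry no population, region, or sex metadata; round trips
  preserve genotypes and individual ids but name populations by the first
  individual label of each block, so region/locality maps must be keyed by
  those names (the pipeline config does this).
- The AMOVA is allele-identity (F_ST-analog) only; no R_ST / allele-size
  variant.
- The bottleneck θ-grid rejection conditions on k only approximately for
  SMM/TPM (exact for IAM, where H | k is θ-free).
- P_ST inherits all caveats of phenotypic proxies for Q_ST: it cannot
  separate plasticity from additive divergence; the critical-ratio report
  is the package's quantification of that sensitivity, not a fix for it.
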