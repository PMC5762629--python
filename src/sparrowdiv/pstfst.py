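"""The core inference: Bayesian variance components, P_ST with credible
intervals, the critical c/h2 ratio, and the P_ST - F_ST verdict.

P_ST approximates Q_ST from phenotypic data alone:

    P_ST = (c/h2 * sigma2_B) / (c/h2 * sigma2_B + 2 * sigma2_W)

with sigma2_B the between-population and sigma2_W the within-population
phenotypic variance and c/h2 the ratio of the between-population additive
proportion to narrow-sense heritability.  Variances come from a Gaussian
random-intercept model fit by Gibbs sampling; P_ST is evaluated per
posterior draw, with the point estimate the posterior median at c/h2 = 1.
A trait's divergence signal is robust when the critical c/h2 -- the ratio
at which the P_ST lower credible bound meets the F_ST upper bound -- is
small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import PhenotypeTable


@dataclass
class ChainSettings:
    iterations: int = 65000
    burn_in: int = 15000
    thin: int = 50
    seed: int = 0

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class VarComponentPosterior:
    trait: str
    sigma2_between: np.ndarray  # retained draws
    sigma2_within: np.ndarray
    fixed_effects: dict[str, np.ndarray]
    chain: ChainSettings
    ess: dict[str, float] = field(default_factory=dict)
    rhat: dict[str, float] = field(default_factory=dict)
    converged: bool = True


def _design(df: pd.DataFrame, fixed_effects: tuple[str, ...]):
    """Intercept + treatment-coded dummies for the requested fixed effects."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for eff in fixed_effects:
        levels = sorted(df[eff].astype(str).unique())
        for lev in levels[1:]:
            cols.append((df[eff].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{eff}[{lev}]")
    return np.column_stack(cols), names


def fit_variance_components(
    phenotypes: PhenotypeTable,
    trait: str,
    fixed_effects: tuple[str, ...] = ("sex",),
    chain: ChainSettings | None = None,
    n_chains: int = 1,
    prior_nu: float = 0.002,
    prior_v: float = 1.0,
) -> VarComponentPosterior:
    """Gibbs sampler for y = X beta + u_pop + e, u ~ N(0, sigma2_B),
    e ~ N(0, sigma2_W).

    Weakly informative inverse-gamma priors on both variances
    (shape nu/2, scale nu*V/2).  Retains (iterations - burn_in)/thin draws
    per chain.  Effective sample size and split-chain R-hat are reported
    for the two variances; the result is flagged non-converged when any
    R-hat exceeds 1.1.
    """
    chain = chain or ChainSettings()
    df = phenotypes.trait_frame(trait)
    pops = sorted(df["population"].unique())
    if len(pops) < 3:
        raise ValueError("need at least 3 populations to separate the variances")
    y = df["value"].to_numpy(dtype=float)
    X, beta_names = _design(df, fixed_effects)
    pop_idx = df["population"].map({p: i for i, p in enumerate(pops)}).to_numpy()
    n, q = len(y), len(pops)
    n_per_pop = np.bincount(pop_idx, minlength=q).astype(float)
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    chol_XtX_inv = np.linalg.cholesky(XtX_inv)
    a0 = prior_nu / 2.0
    b0 = prior_nu * prior_v / 2.0

    draws_b, draws_w, draws_beta = [], [], []
    for c in range(n_chains):
        rng = np.random.default_rng(chain.seed + 7919 * c)
        beta = XtX_inv @ (X.T @ y)
        u = np.zeros(q)
        s2b, s2w = np.var(y) / 2 + 1e-6, np.var(y) / 2 + 1e-6
        keep_b = np.empty(chain.n_retained)
        keep_w = np.empty(chain.n_retained)
        keep_beta = np.empty((chain.n_retained, X.shape[1]))
        kept = 0
        for it in range(chain.iterations):
            # beta | u, s2w
            resid_u = y - u[pop_idx]
            mean_beta = XtX_inv @ (X.T @ resid_u)
            beta = mean_beta + np.sqrt(s2w) * (chol_XtX_inv @ rng.standard_normal(X.shape[1]))
            # u | beta, s2b, s2w
            resid_b = y - X @ beta
            prec = n_per_pop / s2w + 1.0 / s2b
            mean_u = np.bincount(pop_idx, weights=resid_b, minlength=q) / s2w / prec
            u = mean_u + rng.standard_normal(q) / np.sqrt(prec)
            # variances
            s2b = 1.0 / rng.gamma(a0 + q / 2.0, 1.0 / (b0 + 0.5 * np.sum(u**2)))
            e = resid_b - u[pop_idx]
            s2w = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + 0.5 * np.sum(e**2)))
            if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
                if kept < chain.n_retained:
                    keep_b[kept] = s2b
                    keep_w[kept] = s2w
                    keep_beta[kept] = beta
                    kept += 1
        draws_b.append(keep_b[:kept])
        draws_w.append(keep_w[:kept])
        draws_beta.append(keep_beta[:kept])

    b_mat = np.stack(draws_b)  # (chains, draws)
    w_mat = np.stack(draws_w)
    ess, rhat = _diagnostics({"sigma2_between": b_mat, "sigma2_within": w_mat})
    beta_all = np.concatenate(draws_beta, axis=0)
    return VarComponentPosterior(
        trait=trait,
        sigma2_between=b_mat.ravel(),
        sigma2_within=w_mat.ravel(),
        fixed_effects={nm: beta_all[:, k] for k, nm in enumerate(beta_names)},
        chain=chain,
        ess=ess,
        rhat=rhat,
        converged=all(v <= 1.1 for v in rhat.values()),
    )


def _diagnostics(chains: dict[str, np.ndarray]):
    """ESS and split-chain R-hat via arviz (lazy import).

    A single chain is split into halves so R-hat is always defined.
    """
    import logging
    import warnings

    ess, rhat = {}, {}
    logging.getLogger("arviz").setLevel(logging.ERROR)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        for name, mat in chains.items():
            mat = np.asarray(mat)
            ess[name] = float(az.ess(mat))
            if mat.shape[0] == 1:
                half = mat.shape[1] // 2
                split = np.stack([mat[0, :half], mat[0, half : 2 * half]])
            else:
                split = mat
            rhat[name] = float(az.rhat(split))
    return ess, rhat


# ---------------------------------------------------------------------------
# P_ST and the decision framework
# ---------------------------------------------------------------------------

def pst(sigma2_between, sigma2_within, ratio_c_h2: float = 1.0):
    """P_ST = (phi * s2B) / (phi * s2B + 2 * s2W) with phi = c/h2.

    Accepts scalars or arrays of posterior draws (evaluated elementwise).
    """
    if ratio_c_h2 <= 0:
        raise ValueError("c/h2 ratio must be positive")
    s2b = np.asarray(sigma2_between, dtype=float)
    s2w = np.asarray(sigma2_within, dtype=float)
    if (s2w <= 0).any():
        raise ValueError("within-population variance must be positive")
    num = ratio_c_h2 * s2b
    out = num / (num + 2.0 * s2w)
    return float(out) if out.ndim == 0 else out


@dataclass
class PstResult:
    trait: str
    pst_median: float
    ci_low: float
    ci_high: float
    fst_upper_ci: float
    critical_c_h2: float | None  # None when P_ST = F_ST (not defined)
    critical_c_h2_posterior: float | None
    verdict: str  # 'P_ST >> F_ST' | 'P_ST > F_ST' | 'P_ST = F_ST'


def pst_posterior_summary(post: VarComponentPosterior, ratio_c_h2: float = 1.0):
    """(median, 2.5%, 97.5%) of the P_ST posterior at a given c/h2."""
    draws = pst(post.sigma2_between, post.sigma2_within, ratio_c_h2)
    med, lo, hi = np.percentile(draws, [50, 2.5, 97.5])
    return float(med), float(lo), float(hi)


def critical_c_over_h2(pst_lower_ci_at_1: float, fst_upper_ci: float) -> float:
    """Closed-form c/h2 at which the P_ST lower bound meets the F_ST upper
    bound: phi* = [F/(1-F)] * [(1-P_low)/P_low].

    Follows from inverting P_ST(phi) = phi*rho/(phi*rho + 1) with
    rho = P_low/(1-P_low) held at the lower credible bound.
    """
    f, p = fst_upper_ci, pst_lower_ci_at_1
    if not (0 < f < 1 and 0 < p < 1):
        raise ValueError("both bounds must lie in (0, 1)")
    return (f / (1.0 - f)) * ((1.0 - p) / p)


def critical_c_over_h2_posterior(
    post: VarComponentPosterior,
    fst_upper_ci: float,
    tol: float = 1e-6,
) -> float | None:
    """Grid/bisection mode: the phi at which the recomputed 2.5% P_ST
    quantile equals the F_ST upper bound.  None when even phi -> large
    cannot lift the lower bound above F (trait indistinguishable from
    neutral differentiation)."""
    def lower(phi):
        return np.percentile(pst(post.sigma2_between, post.sigma2_within, phi), 2.5)

    lo, hi = 1e-9, 1.0
    while lower(hi) < fst_upper_ci:
        hi *= 2.0
        if hi > 1e9:
            return None
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if lower(mid) < fst_upper_ci:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + tol:
            break
    return float(np.sqrt(lo * hi))


VERDICT_STRONG = "P_ST >> F_ST"
VERDICT_GREATER = "P_ST > F_ST"
VERDICT_EQUAL = "P_ST = F_ST"


def verdict(
    pst_lower_ci: float,
    fst_upper_ci: float,
    critical_c_h2: float | None,
    strong_threshold: float = 0.125,
) -> str:
    """Label the comparison: '=' when the P_ST lower bound does not exceed
    the F_ST upper bound; otherwise '>' upgraded to '>>' when the critical
    c/h2 is at or below ``strong_threshold``."""
    if pst_lower_ci <= fst_upper_ci:
        return VERDICT_EQUAL
    if critical_c_h2 is not None and critical_c_h2 <= strong_threshold:
        return VERDICT_STRONG
    return VERDICT_GREATER


def pst_fst_row(
    post: VarComponentPosterior,
    fst_upper_ci: float,
    strong_threshold: float = 0.125,
    posterior_mode: bool = True,
) -> PstResult:
    """One decision-table row for a trait: P_ST point and CI at c/h2 = 1,
    the critical c/h2 (closed form, plus the posterior-grid recomputation),
    and the verdict."""
    med, lo, hi = pst_posterior_summary(post, 1.0)
    exceeds = lo > fst_upper_ci
    crit = None
    crit_post = None
    if exceeds and 0 < lo < 1:
        crit = critical_c_over_h2(lo, fst_upper_ci)
        if posterior_mode:
            crit_post = critical_c_over_h2_posterior(post, fst_upper_ci)
    return PstResult(
        trait=post.trait,
        pst_median=med,
        ci_low=lo,
        ci_high=hi,
        fst_upper_ci=fst_upper_ci,
        critical_c_h2=crit,
        critical_c_h2_posterior=crit_post,
        verdict=verdict(lo, fst_upper_ci, crit, strong_threshold),
    )


def pst_fst_table(results: list[PstResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                trait=r.trait,
                P_ST=r.pst_median,
                ci_low=r.ci_low,
                ci_high=r.ci_high,
                F_ST_upper=r.fst_upper_ci,
                critical_c_h2=r.critical_c_h2,
                verdict=r.verdict,
            )
            for r in results
        ]
    )
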