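"""Phylogenetic linear mixed model and variance partitioning.

Model for the site-species response (wood density per site-species row):

    y = X beta + Z a + Z s + e,
    a ~ N(0, sigma2_p * Lambda),  s ~ N(0, sigma2_s * I),  e ~ N(0, sigma2_e * I)

where Z maps rows to species, Lambda is the Brownian correlation of the
(pruned) phylogeny rescaled to unit diagonal, a captures shared ancestry,
s captures interspecific variation independent of ancestry (convergent or
divergent recent evolution), and e is the within-species site residual.

Fitting maximizes the marginal likelihood of
y ~ N(X beta, sigma2_p Z Lambda Z' + sigma2_s Z Z' + sigma2_e I)
over the variance components with beta profiled out by generalized least
squares (REML optional); the n x n inverse is avoided via the Woodbury
identity on the species-level (q x q) inner matrix.  A Gibbs sampler
provides the Bayesian analogue with MCMCglmm-style summaries (Post.mean,
95% CI, effective sample size, pMCMC).

The variance partition follows the marginal/conditional R2 conventions:
with total = s2f + s2p + s2s + s2e (s2f the variance of the fixed-effect
predictor across rows),

    R2p = s2p / total          (phylogeny)
    R2s = s2s / total          (species)
    R2c = (s2f + s2p + s2s) / total   (whole model)
    R2m = s2f / total          (fixed effects; marginal R2)

An alternative R2m = s2f / (s2f + s2e) -- the share of the
non-(phylogeny+species) variance captured by the fixed effects -- is
available via ``r2m_convention="residual"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .treekit import PhyloCovariance, PhyloTree, build_vcv, extract_subtree

__all__ = [
    "PMMDesign",
    "PMMFit",
    "ImportanceResult",
    "NotIdentifiableError",
    "build_design",
    "marginal_loglik",
    "fit_pmm_ml",
    "fit_pmm_mcmc",
    "variance_partition",
    "select_fixed_effects",
    "env_only_r2",
    "permutation_importance",
    "score_single_permutation",
    "partial_effects",
]

_LOG2PI = math.log(2.0 * math.pi)


class NotIdentifiableError(ValueError):
    """The design cannot separate the requested variance components."""


# ---------------------------------------------------------------------------
# design


@dataclass
class PMMDesign:
    """Response, fixed design, species index, and phylogenetic correlation.

    ``Lambda`` is species-by-species with unit diagonal, ordered like
    ``species_labels``; ``codes`` holds each row's index into that order.
    """

    y: np.ndarray
    X: np.ndarray
    fixed_names: tuple[str, ...]
    codes: np.ndarray
    species_labels: tuple[str, ...]
    Lambda: np.ndarray
    standardized: bool = False
    n_dropped: int = 0

    @property
    def n_rows(self) -> int:
        return self.y.size

    @property
    def n_species(self) -> int:
        return len(self.species_labels)

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.codes, minlength=self.n_species)


def build_design(table: pd.DataFrame, tree: PhyloTree, fixed,
                 standardize: bool = False,
                 response: str = "wood_density") -> PMMDesign:
    """Assemble a PMM design from a site-species table and a tree.

    The tree is pruned to the table's species; table rows whose species is
    absent from the tree are dropped (count recorded on the design).
    Lambda is the Brownian covariance rescaled to a correlation matrix.
    Covariates are used raw by default (coefficients per natural unit);
    ``standardize=True`` z-scores them.
    """
    fixed = list(fixed)
    for col in fixed + [response, "species"]:
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
        if col != "species" and table[col].isna().any():
            raise ValueError(f"column {col!r} has missing values")

    tips = set(tree.tip_labels)
    in_tree = table["species"].isin(tips)
    n_dropped = int((~in_tree).sum())
    kept = table.loc[in_tree]
    if kept.empty:
        raise ValueError("no species shared between table and tree")

    species_labels = tuple(sorted(kept["species"].unique()))
    sub = extract_subtree(tree, species_labels)
    C = build_vcv(sub).submatrix(species_labels)
    d = np.sqrt(np.diag(C.matrix))
    Lambda = C.matrix / np.outer(d, d)

    idx = {sp: i for i, sp in enumerate(species_labels)}
    codes = kept["species"].map(idx).to_numpy()

    Xcov = kept[fixed].to_numpy(dtype=float)
    if standardize and Xcov.size:
        Xcov = (Xcov - Xcov.mean(axis=0)) / Xcov.std(axis=0, ddof=1)
    X = np.column_stack([np.ones(len(kept)), Xcov])
    return PMMDesign(
        y=kept[response].to_numpy(dtype=float),
        X=X,
        fixed_names=("intercept", *fixed),
        codes=codes,
        species_labels=species_labels,
        Lambda=Lambda,
        standardized=standardize,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# marginal likelihood (Woodbury on the species-level inner matrix)


class _VInverse:
    """Operator for V = s2e I + Z A Z' with A = s2p Lambda + s2s I."""

    def __init__(self, design: PMMDesign, s2p: float, s2s: float, s2e: float):
        if s2e <= 0:
            raise ValueError("sigma2_e must be > 0")
        q = design.n_species
        self.design = design
        self.s2e = s2e
        self.direct = (s2p + s2s) <= 1e-14
        if self.direct:
            self.logdet = design.n_rows * math.log(s2e)
            return
        A = s2p * design.Lambda + s2s * np.eye(q)
        # factor A = L L' and work with M = I + L' Z'Z L / s2e, which avoids
        # an explicit A inverse (Z'Z is diagonal with the species counts)
        L = np.linalg.cholesky(A)
        self._L = L
        M = np.eye(q) + (L.T * design.counts) @ L / s2e
        cfM = cho_factor(M, lower=True)
        self._cfM = cfM
        logdetM = 2.0 * np.sum(np.log(np.diag(cfM[0])))
        self.logdet = logdetM + design.n_rows * math.log(s2e)

    def dot(self, B: np.ndarray) -> np.ndarray:
        """V^{-1} B for a vector or matrix B."""
        B2 = B[:, None] if B.ndim == 1 else B
        if self.direct:
            out = B2 / self.s2e
        else:
            ZtB = np.zeros((self.design.n_species, B2.shape[1]))
            np.add.at(ZtB, self.design.codes, B2)
            W = self._L @ cho_solve(self._cfM, self._L.T @ ZtB)
            out = B2 / self.s2e - W[self.design.codes, :] / self.s2e**2
        return out[:, 0] if B.ndim == 1 else out


def _gls(design: PMMDesign, vinv: _VInverse):
    X = design.X
    ViX = vinv.dot(X)
    XtViX = X.T @ ViX
    XtViy = ViX.T @ design.y
    beta = np.linalg.solve(XtViX, XtViy)
    return beta, XtViX


def marginal_loglik(design: PMMDesign, sigma2_p: float, sigma2_s: float,
                    sigma2_e: float, beta=None, reml: bool = False) -> float:
    """Marginal log-likelihood of the PMM at the given variance components.

    With ``beta=None`` the fixed effects are profiled out by GLS.  The
    computation factorizes the q x q species-level matrix (Woodbury), never
    the n x n covariance.
    """
    vinv = _VInverse(design, sigma2_p, sigma2_s, sigma2_e)
    if beta is None:
        beta, XtViX = _gls(design, vinv)
    else:
        beta = np.asarray(beta, dtype=float)
        XtViX = None
    r = design.y - design.X @ beta
    quad = float(r @ vinv.dot(r))
    n = design.n_rows
    ll = -0.5 * (n * _LOG2PI + vinv.logdet + quad)
    if reml:
        if XtViX is None:
            _, XtViX = _gls(design, vinv)
        sign, logdetX = np.linalg.slogdet(XtViX)
        p = design.X.shape[1]
        ll += -0.5 * logdetX + 0.5 * p * _LOG2PI
    return float(ll)


# ---------------------------------------------------------------------------
# variance partition


def variance_partition(sigma2_f: float, sigma2_p: float, sigma2_s: float,
                       sigma2_e: float, r2m_convention: str = "total") -> dict:
    """Fractions of response variance by source.

    total = s2f + s2p + s2s + s2e.  R2p = s2p/total, R2s = s2s/total,
    R2c = (s2f+s2p+s2s)/total.  R2m defaults to s2f/total (marginal R2,
    consistent with the conditional/marginal decomposition); the
    ``"residual"`` convention returns s2f/(s2f+s2e) instead.
    """
    comps = dict(sigma2_f=sigma2_f, sigma2_p=sigma2_p, sigma2_s=sigma2_s,
                 sigma2_e=sigma2_e)
    for name, v in comps.items():
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    total = sum(comps.values())
    if total <= 0:
        raise ValueError("all variance components are zero")
    if r2m_convention == "total":
        r2m = sigma2_f / total
    elif r2m_convention == "residual":
        denom = sigma2_f + sigma2_e
        r2m = sigma2_f / denom if denom > 0 else 0.0
    else:
        raise ValueError("r2m_convention must be 'total' or 'residual'")
    return {
        "R2m": r2m,
        "R2c": (sigma2_f + sigma2_p + sigma2_s) / total,
        "R2p": sigma2_p / total,
        "R2s": sigma2_s / total,
    }


# ---------------------------------------------------------------------------
# ML / REML fit


@dataclass
class PMMFit:
    """Fitted PMM: fixed effects, variance components, and partition."""

    beta: pd.DataFrame
    sigma2_p: float
    sigma2_s: float
    sigma2_e: float
    sigma2_f: float
    loglik: float
    partition: dict
    method: str
    design: PMMDesign
    converged: bool = True
    warnings: list[str] = field(default_factory=list)
    mcmc: pd.DataFrame | None = None
    chain: pd.DataFrame | None = None

    def summary(self) -> str:
        parts = [f"PMM fit ({self.method}); loglik={self.loglik:.3f}",
                 self.beta.to_string(),
                 "variance components: "
                 f"s2p={self.sigma2_p:.5g} s2s={self.sigma2_s:.5g} "
                 f"s2e={self.sigma2_e:.5g} s2f={self.sigma2_f:.5g}",
                 "partition: " + " ".join(f"{k}={v:.3f}"
                                          for k, v in self.partition.items())]
        return "\n".join(parts)


def _identifiability_checks(design: PMMDesign) -> list[str]:
    warns = []
    counts = design.counts
    if np.all(counts == 1):
        raise NotIdentifiableError(
            "every species has exactly one row, so sigma2_s and sigma2_e are"
            " not separable; aggregate replicate measurements per site first"
            " or drop the species term"
        )
    q = design.n_species
    if np.max(np.abs(design.Lambda - np.eye(q))) < 1e-9:
        warns.append(
            "phylogenetic correlation equals identity: sigma2_p and sigma2_s"
            " are jointly unidentifiable (only their sum is estimable)"
        )
    return warns


def fit_pmm_ml(design: PMMDesign, reml: bool = False, n_starts: int = 3,
               tol: float = 1e-8, r2m_convention: str = "total") -> PMMFit:
    """Maximize the (restricted) marginal likelihood over the variances.

    Variances are optimized on the log scale with multiple starts; beta is
    profiled by GLS.  Returns the fit with the variance partition.
    """
    if design.n_rows <= design.X.shape[1] + 3:
        raise ValueError("too few rows for the number of fixed effects")
    warns = _identifiability_checks(design)

    vy = float(np.var(design.y, ddof=1))
    if vy <= 0:
        raise ValueError("response is constant")
    lo, hi = math.log(vy * 1e-8), math.log(vy * 1e3)

    def nll(theta: np.ndarray) -> float:
        s2p, s2s, s2e = np.exp(theta)
        try:
            return -marginal_loglik(design, s2p, s2s, s2e, reml=reml)
        except np.linalg.LinAlgError:
            return 1e12

    starts = [
        np.log(np.array([vy / 3, vy / 3, vy / 3])),
        np.log(np.array([0.8 * vy, 0.1 * vy, 0.1 * vy])),
        np.log(np.array([0.05 * vy, 0.05 * vy, 0.9 * vy])),
    ][:max(1, n_starts)]

    best = None
    last = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                bounds=[(lo, hi)] * 3,
                                options={"ftol": tol, "gtol": 1e-8,
                                         "maxiter": 500})
        last = res
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        grad = np.linalg.norm(getattr(last, "jac", np.array([np.nan])))
        raise RuntimeError(
            f"PMM optimization failed to converge; last iterate "
            f"{np.exp(last.x)}, gradient norm {grad:.3g}"
        )
    converged = bool(best.success)

    s2p, s2s, s2e = np.exp(best.x)
    # components pinned at the lower bound are reported as zero
    floor = vy * 1e-7
    s2p = 0.0 if s2p < floor else float(s2p)
    s2s = 0.0 if s2s < floor else float(s2s)
    s2e = float(s2e)

    vinv = _VInverse(design, max(s2p, 1e-14 * vy), max(s2s, 1e-14 * vy), s2e)
    beta_hat, XtViX = _gls(design, vinv)
    cov_beta = np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))
    z = beta_hat / se
    beta = pd.DataFrame({
        "estimate": beta_hat,
        "se": se,
        "lower95": beta_hat - 1.959963984540054 * se,
        "upper95": beta_hat + 1.959963984540054 * se,
        "p": 2 * stats.norm.sf(np.abs(z)),
    }, index=list(design.fixed_names))

    pred = design.X @ beta_hat
    s2f = float(np.var(pred, ddof=1)) if design.X.shape[1] > 1 else 0.0
    ll = marginal_loglik(design, max(s2p, 1e-14 * vy), max(s2s, 1e-14 * vy),
                         s2e, reml=reml)
    part = variance_partition(s2f, s2p, s2s, s2e, r2m_convention)
    return PMMFit(beta, s2p, s2s, s2e, s2f, ll, part,
                  "reml" if reml else "ml", design, converged, warns)


# ---------------------------------------------------------------------------
# Gibbs sampler (Bayesian backend)


def _rinvgamma(rng, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


def fit_pmm_mcmc(design: PMMDesign, n_iter: int = 6000, burnin: int = 1000,
                 thin: int = 5, seed: int | None = None,
                 prior_shape: float = 0.001, prior_scale: float = 0.001,
                 r2m_convention: str = "total") -> PMMFit:
    """Gibbs sampler for the PMM with conjugate updates.

    Priors: flat normal on beta, inverse-gamma(prior_shape, prior_scale) on
    each variance (weakly informative by default).  The location block
    (beta, a, s) is sampled jointly -- conditioning beta on the species
    effects would mix poorly because the intercept is nearly collinear
    with the mean of the phylogenetic effects.  Summaries per fixed effect follow the
    MCMCglmm conventions: posterior mean, central 95% interval, effective
    sample size, and pMCMC = 2 * min(P(beta > 0), P(beta < 0)).  A warning
    is recorded when any parameter's effective sample size falls below 50.
    """
    import arviz as az

    if n_iter <= burnin:
        raise ValueError("n_iter must exceed burnin")
    warns = _identifiability_checks(design)
    rng = np.random.default_rng(seed)

    y, X, codes = design.y, design.X, design.codes
    n, p = X.shape
    q = design.n_species
    counts = design.counts
    vy = float(np.var(y, ddof=1))

    from scipy.linalg import solve_triangular

    Lam_inv = cho_solve(cho_factor(design.Lambda + 1e-10 * np.eye(q),
                                   lower=True), np.eye(q))
    XtX = X.T @ X
    ZtX = np.zeros((q, p))
    np.add.at(ZtX, codes, X)
    Zty = np.zeros(q)
    np.add.at(Zty, codes, y)
    Xty = X.T @ y
    D = np.diag(counts.astype(float))
    Iq = np.eye(q)
    rhs0 = np.concatenate([Xty, Zty, Zty])

    # state
    s2p, s2s, s2e = vy / 3, vy / 3, vy / 3

    keep_iters = range(burnin, n_iter, thin)
    n_keep = len(keep_iters)
    draws_beta = np.empty((n_keep, p))
    draws_var = np.empty((n_keep, 3))
    draws_s2f = np.empty(n_keep)
    ki = 0

    dim = p + 2 * q
    for it in range(n_iter):
        # joint location block (beta, a, s) | variances
        P = np.empty((dim, dim))
        P[:p, :p] = XtX
        P[:p, p:p + q] = ZtX.T
        P[:p, p + q:] = ZtX.T
        P[p:p + q, :p] = ZtX
        P[p + q:, :p] = ZtX
        P[p:p + q, p:p + q] = D
        P[p:p + q, p + q:] = D
        P[p + q:, p:p + q] = D
        P[p + q:, p + q:] = D
        P /= s2e
        P[p:p + q, p:p + q] += Lam_inv / s2p
        P[p + q:, p + q:] += Iq / s2s
        cfP = cho_factor(P, lower=True)
        mean_t = cho_solve(cfP, rhs0 / s2e)
        z = rng.standard_normal(dim)
        theta = mean_t + solve_triangular(cfP[0], z, lower=True, trans="T")
        beta, a, s = theta[:p], theta[p:p + q], theta[p + q:]

        # variances | rest
        s2p = _rinvgamma(rng, prior_shape + q / 2,
                         prior_scale + 0.5 * float(a @ (Lam_inv @ a)))
        s2s = _rinvgamma(rng, prior_shape + q / 2,
                         prior_scale + 0.5 * float(s @ s))
        e = y - X @ beta - a[codes] - s[codes]
        s2e = _rinvgamma(rng, prior_shape + n / 2,
                         prior_scale + 0.5 * float(e @ e))

        if it in keep_iters:
            draws_beta[ki] = beta
            draws_var[ki] = (s2p, s2s, s2e)
            draws_s2f[ki] = np.var(X @ beta, ddof=1) if p > 1 else 0.0
            ki += 1

    # summaries
    names = list(design.fixed_names)
    rows = []
    ess_all = []
    for j, name in enumerate(names):
        d = draws_beta[:, j]
        ess = float(az.ess(d))
        ess_all.append(ess)
        p_gt = float(np.mean(d > 0))
        rows.append({
            "Post.mean": float(d.mean()),
            "lower95": float(np.quantile(d, 0.025)),
            "upper95": float(np.quantile(d, 0.975)),
            "Eff.samp": ess,
            "pMCMC": min(1.0, 2 * min(p_gt, 1 - p_gt)),
        })
    mcmc_summary = pd.DataFrame(rows, index=names)
    for j, vname in enumerate(["sigma2_p", "sigma2_s", "sigma2_e"]):
        ess_all.append(float(az.ess(draws_var[:, j])))
    if min(ess_all) < 50:
        warns.append(
            f"low effective sample size (min {min(ess_all):.0f} < 50);"
            " consider longer chains"
        )

    s2p_m, s2s_m, s2e_m = draws_var.mean(axis=0)
    s2f_m = float(draws_s2f.mean())
    part_draws = np.array([
        list(variance_partition(f, vp, vs, ve, r2m_convention).values())
        for f, (vp, vs, ve) in zip(draws_s2f, draws_var)
    ])
    part = dict(zip(["R2m", "R2c", "R2p", "R2s"], part_draws.mean(axis=0)))

    beta_mean = draws_beta.mean(axis=0)
    beta_df = pd.DataFrame({
        "estimate": beta_mean,
        "se": draws_beta.std(axis=0, ddof=1),
        "lower95": mcmc_summary["lower95"],
        "upper95": mcmc_summary["upper95"],
        "p": mcmc_summary["pMCMC"],
    }, index=names)

    chain = pd.DataFrame(
        np.column_stack([draws_beta, draws_var, draws_s2f]),
        columns=[*names, "sigma2_p", "sigma2_s", "sigma2_e", "sigma2_f"],
    )
    ll = marginal_loglik(design, max(s2p_m, 1e-14 * vy),
                         max(s2s_m, 1e-14 * vy), s2e_m, beta=beta_mean)
    return PMMFit(beta_df, float(s2p_m), float(s2s_m), float(s2e_m), s2f_m,
                  ll, part, "mcmc", design, True, warns,
                  mcmc=mcmc_summary, chain=chain)


# ---------------------------------------------------------------------------
# fixed-effect subset selection (OLS screen)


@dataclass
class SelectionResult:
    best: tuple[str, ...]
    table: pd.DataFrame
    criterion: str


def select_fixed_effects(table: pd.DataFrame, candidates,
                         criterion: str = "aic",
                         response: str = "wood_density") -> SelectionResult:
    """Exhaustive subset selection with an ordinary-least-squares screen.

    All 2^k candidate subsets are ranked by the chosen information
    criterion ("aic", "aicc", or "bic"); AIC is the default screening
    surrogate.  Note that AIC retains a pure-noise candidate with
    asymptotic probability P(chi2_1 > 2) ~ 0.16, so exact-support recovery
    needs the consistent "bic" setting.  Ties within 1e-9 go to the
    smaller subset, then lexicographic order.
    """
    candidates = list(candidates)
    if len(candidates) > 12:
        raise ValueError(
            "more than 12 candidates; pre-filter before exhaustive search"
        )
    if criterion not in ("aic", "aicc", "bic"):
        raise ValueError("criterion must be 'aic', 'aicc', or 'bic'")
    for col in candidates + [response]:
        if col not in table.columns or table[col].isna().any():
            raise ValueError(f"column {col!r} missing or incomplete")

    y = table[response].to_numpy(dtype=float)
    n = y.size
    rows = []
    for size in range(len(candidates) + 1):
        for subset in combinations(sorted(candidates), size):
            X = sm.add_constant(table[list(subset)].to_numpy(dtype=float),
                                has_constant="add")
            res = sm.OLS(y, X).fit()
            k = X.shape[1] + 1  # + residual variance
            aic = float(res.aic)
            aicc = aic + 2.0 * k * (k + 1) / max(n - k - 1, 1)
            rows.append({
                "subset": subset,
                "n_terms": size,
                "aic": aic,
                "aicc": aicc,
                "bic": float(res.bic),
                "r2": float(res.rsquared),
                "loglik": float(res.llf),
            })
    tab = pd.DataFrame(rows).sort_values(criterion, kind="mergesort",
                                         ignore_index=True)
    best_ic = tab[criterion].iloc[0]
    tied = tab[tab[criterion] <= best_ic + 1e-9]
    best = min(tied["subset"], key=lambda s: (len(s), s))
    return SelectionResult(tuple(best), tab, criterion)


# ---------------------------------------------------------------------------
# environment-only regression


@dataclass
class EnvRegression:
    r2: float
    coefficients: pd.DataFrame
    nobs: int


def env_only_r2(table: pd.DataFrame, fixed,
                response: str = "wood_density") -> EnvRegression:
    """OLS of the trait on environmental covariates; unadjusted R^2.

    This is the environment-explained share of trait variance when
    phylogeny and species are ignored (the multiple-regression complement
    to the mixed-model partition).
    """
    fixed = list(fixed)
    for col in fixed + [response]:
        if col not in table.columns or table[col].isna().any():
            raise ValueError(f"column {col!r} missing or incomplete")
    Xraw = table[fixed].to_numpy(dtype=float)
    X = sm.add_constant(Xraw, has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        offenders = []
        for j, name in enumerate(fixed):
            others = np.delete(X, j + 1, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                offenders.append(name)
        raise ValueError(f"rank-deficient design; collinear columns: {offenders}")
    res = sm.OLS(table[response].to_numpy(dtype=float), X).fit()
    ci = res.conf_int()
    coef = pd.DataFrame({
        "estimate": res.params,
        "se": res.bse,
        "lower95": ci[:, 0],
        "upper95": ci[:, 1],
        "p": res.pvalues,
    }, index=["intercept", *fixed])
    return EnvRegression(float(res.rsquared), coef, int(res.nobs))


# ---------------------------------------------------------------------------
# permutation importance


@dataclass
class ImportanceResult:
    """%IncMSE-style permutation importance for a fitted predictor."""

    scores: pd.DataFrame
    n_repeats: int
    seed: int | None


def _predict(predictor, table: pd.DataFrame) -> np.ndarray:
    fn = predictor.predict if hasattr(predictor, "predict") else predictor
    return np.asarray(fn(table), dtype=float)


def score_single_permutation(predictor, table: pd.DataFrame, variable: str,
                             perm: np.ndarray,
                             response: str = "wood_density") -> float:
    """Relative MSE increase (in %) for one explicit permutation.

    The identity permutation scores exactly 0.
    """
    y = table[response].to_numpy(dtype=float)
    base = float(np.mean((y - _predict(predictor, table)) ** 2))
    shuffled = table.copy()
    shuffled[variable] = shuffled[variable].to_numpy()[perm]
    mse = float(np.mean((y - _predict(predictor, shuffled)) ** 2))
    return (mse - base) / base * 100.0


def permutation_importance(predictor, table: pd.DataFrame, variables,
                           n_repeats: int = 20, seed: int | None = None,
                           response: str = "wood_density") -> ImportanceResult:
    """Permutation importance around a caller-supplied fitted predictor.

    For each variable the score is the mean over ``n_repeats`` shuffles of
    (MSE_permuted - MSE_baseline) / MSE_baseline * 100 -- the %IncMSE
    convention.  Ranks are 1..k in descending score order.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    variables = list(variables)
    rng = np.random.default_rng(seed)
    y = table[response].to_numpy(dtype=float)
    base = float(np.mean((y - _predict(predictor, table)) ** 2))
    n = len(table)

    rows = []
    for var in variables:
        col = table[var].to_numpy()
        scores = np.empty(n_repeats)
        shuffled = table.copy()
        for rep in range(n_repeats):
            shuffled[var] = col[rng.permutation(n)]
            mse = float(np.mean((y - _predict(predictor, shuffled)) ** 2))
            scores[rep] = (mse - base) / base * 100.0
        shuffled[var] = col
        rows.append({"variable": var, "score": float(scores.mean()),
                     "se": float(scores.std(ddof=1) / math.sqrt(n_repeats))
                     if n_repeats > 1 else math.nan})
    df = pd.DataFrame(rows).sort_values("score", ascending=False,
                                        kind="mergesort", ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return ImportanceResult(df, n_repeats, seed)


# ---------------------------------------------------------------------------
# partial effects


@dataclass
class PartialEffect:
    variable: str
    slope: float
    sign: str
    lower95: float
    upper95: float
    points: pd.DataFrame


def partial_effects(fit, variable: str, table: pd.DataFrame | None = None,
                    response: str = "wood_density") -> PartialEffect:
    """Partial-residual pairs and the fitted partial slope for a variable.

    Accepts a :class:`PMMFit` (uses its design) or an
    :class:`EnvRegression` with its ``table``.  The partial residual adds
    the variable's own contribution back onto the model residual, so the
    scatter's slope is the fitted coefficient; the reported sign is the
    effect direction.
    """
    if isinstance(fit, PMMFit):
        names = list(fit.design.fixed_names)
        if variable not in names:
            raise KeyError(f"variable {variable!r} not in the fit")
        j = names.index(variable)
        beta = fit.beta["estimate"].to_numpy()
        x = fit.design.X[:, j]
        resid = fit.design.y - fit.design.X @ beta
        lower = float(fit.beta["lower95"].iloc[j])
        upper = float(fit.beta["upper95"].iloc[j])
        slope = float(beta[j])
    elif isinstance(fit, EnvRegression):
        if table is None:
            raise ValueError("table is required with an EnvRegression fit")
        names = list(fit.coefficients.index)
        if variable not in names:
            raise KeyError(f"variable {variable!r} not in the fit")
        j = names.index(variable)
        beta = fit.coefficients["estimate"].to_numpy()
        X = sm.add_constant(table[names[1:]].to_numpy(dtype=float),
                            has_constant="add")
        x = X[:, j]
        resid = table[response].to_numpy(dtype=float) - X @ beta
        lower = float(fit.coefficients["lower95"].iloc[j])
        upper = float(fit.coefficients["upper95"].iloc[j])
        slope = float(beta[j])
    else:
        raise TypeError("fit must be a PMMFit or EnvRegression")
    partial = resid + slope * x
    points = pd.DataFrame({variable: x, "partial_residual": partial})
    return PartialEffect(variable, slope, "+" if slope >= 0 else "-",
                         lower, upper, points)
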