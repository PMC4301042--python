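"""Random-intercept models for species comparisons within a microhabitat.

One grouping factor (the 1 m^2 subplot) and one fixed factor (species) —
the structure the whole analysis rests on:

    gaussian:  y_ij = mu + beta_{s(ij)} + u_j + e_ij,
               u_j ~ N(0, sigma_u^2), e_ij ~ N(0, sigma_e^2)
    binomial:  logit P(y_ij = 1) = mu + beta_{s(ij)} + u_j

The gaussian model is fitted by REML with the variance ratio
lambda = sigma_u^2 / sigma_e^2 profiled out by one-dimensional numerical
optimization; the single-grouping-factor structure lets the objective be
assembled from per-subplot sufficient statistics without forming any n x n
matrix. The binomial model is fitted by maximum likelihood under the
Laplace approximation (per-subplot Newton inner modes, quasi-Newton outer
optimization) with fixed zero starting values.

Downstream: least-squares means per species (marginal means at random
effect zero), all pairwise z contrasts, and the Shaffer S1 step-down
multiplicity correction whose multipliers come from enumerating the
attainable numbers of true pairwise-equality hypotheses (set partitions
of the species).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import norm

ALPHA_DEFAULT = 0.05
REML_REL_TOL = 1e-8
_LOG_LAMBDA_GRID = np.linspace(-12.0, 8.0, 81)  # profiled ratio search grid
_RIDGE_SEPARATION = 1e-4


class InferenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Fit containers


@dataclass
class ModelFit:
    family: str  # "gaussian" | "binomial"
    species_levels: list[str]
    beta: np.ndarray  # intercept + reference-coded species effects
    vcov_fixed: np.ndarray
    sigma_u2: float
    sigma_e2: float  # NaN for binomial
    loglik: float  # REML (gaussian) or Laplace ML (binomial)
    n_obs: int
    n_groups: int
    separation: bool = False


@dataclass
class LSMeans:
    species: list[str]
    estimate: np.ndarray  # response scale (gaussian) / log-odds (binomial)
    se: np.ndarray
    probability: np.ndarray | None = None  # binomial only


@dataclass
class PairwiseContrast:
    species_a: str
    species_b: str
    estimate: float
    se: float
    z: float
    p_raw: float
    p_adjusted: float = np.nan


# ---------------------------------------------------------------------------
# Design helpers


def _design(species_factor, subplot_factor):
    species = np.asarray(species_factor)
    subplot = np.asarray(subplot_factor)
    levels = sorted(set(species.tolist()))
    if len(levels) < 2:
        raise InferenceError("need >= 2 species levels")
    counts = {lv: int(np.sum(species == lv)) for lv in levels}
    empty = [lv for lv, c in counts.items() if c == 0]
    if empty:
        raise InferenceError(f"species level with 0 observations: {empty}")
    n = len(species)
    X = np.ones((n, len(levels)))
    for k, lv in enumerate(levels[1:], start=1):
        X[:, k] = (species == lv).astype(float)
    glabels, gidx = np.unique(subplot, return_inverse=True)
    if len(glabels) < 2:
        raise InferenceError("need >= 2 subplots")
    return X, levels, gidx, len(glabels)


# ---------------------------------------------------------------------------
# Gaussian REML with profiled variance ratio


class _REMLProfile:
    """Per-group sufficient statistics for the profiled REML objective."""

    def __init__(self, X, y, gidx, n_groups):
        self.X = X
        self.y = y
        self.n, self.p = X.shape
        self.G = n_groups
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # A[:, g] = X' 1_g ; b[g] = 1_g' y ; ng[g] = group size
        self.A = np.zeros((self.p, n_groups))
        self.b = np.zeros(n_groups)
        np.add.at(self.A.T, gidx, X)
        np.add.at(self.b, gidx, y)
        self.ng = np.bincount(gidx, minlength=n_groups).astype(float)

    def solve(self, lam: float):
        """GLS pieces at variance ratio lam (V* = I + lam Z Z')."""
        w = lam / (1.0 + self.ng * lam)  # shrinkage weight per group
        XtVX = self.XtX - (self.A * w) @ self.A.T
        XtVy = self.Xty - self.A @ (w * self.b)
        ytVy = self.yty - float(w @ (self.b**2))
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - float(beta @ XtVy)  # r' V*^-1 r at GLS beta
        return beta, XtVX, max(rss, 1e-300)

    def neg_reml(self, log_lam: float) -> float:
        lam = np.exp(log_lam)
        _, XtVX, rss = self.solve(lam)
        nmp = self.n - self.p
        logdet_v = float(np.sum(np.log1p(self.ng * lam)))
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        # REML deviance up to an additive constant
        return nmp * np.log(rss) + logdet_v + logdet_x

    def neg_reml_ols(self) -> float:
        """Objective at the lam = 0 boundary (ordinary least squares)."""
        beta = np.linalg.solve(self.XtX, self.Xty)
        rss = max(self.yty - float(beta @ self.Xty), 1e-300)
        sign, logdet_x = np.linalg.slogdet(self.XtX)
        return (self.n - self.p) * np.log(rss) + logdet_x


def fit_gaussian_lmm(y, species_factor, subplot_factor) -> ModelFit:
    """REML fit of the gaussian random-intercept model.

    The variance ratio is profiled on a log grid, then refined by bounded
    scalar minimization around the best grid point; a boundary optimum
    falls back to ordinary least squares (sigma_u^2 = 0).
    """
    y = np.asarray(y, dtype=float)
    X, levels, gidx, G = _design(species_factor, subplot_factor)
    n, p = X.shape
    if n <= p:
        raise InferenceError("n_obs must exceed the number of fixed effects")
    prof = _REMLProfile(X, y, gidx, G)

    grid_vals = np.array([prof.neg_reml(ll) for ll in _LOG_LAMBDA_GRID])
    k = int(np.argmin(grid_vals))
    lo = _LOG_LAMBDA_GRID[max(k - 1, 0)]
    hi = _LOG_LAMBDA_GRID[min(k + 1, len(_LOG_LAMBDA_GRID) - 1)]
    res = optimize.minimize_scalar(
        prof.neg_reml,
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    best_ll = res.x if res.fun <= grid_vals[k] else _LOG_LAMBDA_GRID[k]
    obj = min(float(res.fun), float(grid_vals[k]))

    obj_ols = prof.neg_reml_ols()
    if obj_ols <= obj + REML_REL_TOL * abs(obj):
        lam = 0.0
        obj = obj_ols
    else:
        lam = float(np.exp(best_ll))

    beta, XtVX, rss = prof.solve(lam) if lam > 0 else (None, None, None)
    if lam == 0.0:
        XtVX = prof.XtX
        beta = np.linalg.solve(XtVX, prof.Xty)
        rss = max(prof.yty - float(beta @ prof.Xty), 1e-300)
    sigma_e2 = rss / (n - p)
    vcov = sigma_e2 * np.linalg.inv(XtVX)
    logdet_v = float(np.sum(np.log1p(prof.ng * lam)))
    sign, logdet_x = np.linalg.slogdet(XtVX)
    loglik = -0.5 * (
        (n - p) * (1.0 + np.log(2.0 * np.pi * sigma_e2)) + logdet_v + logdet_x
    )
    return ModelFit(
        family="gaussian",
        species_levels=levels,
        beta=beta,
        vcov_fixed=vcov,
        sigma_u2=lam * sigma_e2,
        sigma_e2=sigma_e2,
        loglik=float(loglik),
        n_obs=n,
        n_groups=G,
    )


# ---------------------------------------------------------------------------
# Binomial GLMM via Laplace approximation


class _LaplaceObjective:
    def __init__(self, X, y, gidx, n_groups, ridge=0.0):
        self.X = X
        self.y = y.astype(float)
        self.gidx = gidx
        self.G = n_groups
        self.ridge = ridge
        self._u = np.zeros(n_groups)  # warm-started inner modes

    def _inner_modes(self, eta_fixed, sigma2):
        """Newton iterations for each subplot's conditional mode (vectorized)."""
        u = self._u.copy()
        for _ in range(50):
            eta = eta_fixed + u[self.gidx]
            p = special.expit(eta)
            g1 = np.zeros(self.G)
            np.add.at(g1, self.gidx, self.y - p)
            g1 -= u / sigma2
            w = np.zeros(self.G)
            np.add.at(w, self.gidx, p * (1.0 - p))
            h = w + 1.0 / sigma2
            step = g1 / h
            u = u + step
            if np.max(np.abs(step)) < 1e-10:
                break
        self._u = u
        return u

    def __call__(self, params) -> float:
        beta = params[:-1]
        sigma2 = np.exp(params[-1])
        eta_fixed = self.X @ beta
        u = self._inner_modes(eta_fixed, sigma2)
        eta = eta_fixed + u[self.gidx]
        # Bernoulli loglik sum per group
        ll_obs = self.y * eta - np.logaddexp(0.0, eta)
        ll = float(np.sum(ll_obs))
        p = special.expit(eta)
        w = np.zeros(self.G)
        np.add.at(w, self.gidx, p * (1.0 - p))
        ll -= 0.5 * float(np.sum(u**2)) / sigma2
        ll -= 0.5 * float(np.sum(np.log1p(sigma2 * w)))
        if self.ridge > 0:
            ll -= 0.5 * self.ridge * float(beta @ beta)
        return -ll


def _detect_separation(y, species):
    levels = sorted(set(np.asarray(species).tolist()))
    y = np.asarray(y, dtype=float)
    for lv in levels:
        ys = y[np.asarray(species) == lv]
        if len(ys) and (np.all(ys == 1.0) or np.all(ys == 0.0)):
            return True
    return False


def fit_binomial_glmm(
    y01, species_factor, subplot_factor, fixed_sigma_u2: float | None = None
) -> ModelFit:
    """Laplace ML fit of the logistic random-intercept model.

    Deterministic: zero starting values for the fixed effects and
    log-variance, warm-started inner Newton modes, BFGS outer optimization.
    Complete separation by species is flagged and stabilized with a small
    ridge on the fixed effects so the estimate stays finite. With
    ``fixed_sigma_u2=0`` the model reduces exactly to ordinary logistic
    regression (no integral to approximate).
    """
    y = np.asarray(y01, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise InferenceError("binomial response must be 0/1")
    if len(set(y.tolist())) < 2:
        raise InferenceError("both outcomes must be present")
    X, levels, gidx, G = _design(species_factor, subplot_factor)
    n, p = X.shape

    separation = _detect_separation(y, species_factor)
    ridge = _RIDGE_SEPARATION if separation else 0.0

    if fixed_sigma_u2 == 0.0:
        # plain logistic regression MLE over beta only
        def glm_obj(beta):
            eta = X @ beta
            nll = -float(np.sum(y * eta - np.logaddexp(0.0, eta)))
            if ridge > 0:
                nll += 0.5 * ridge * float(beta @ beta)
            return nll

        res = optimize.minimize(
            glm_obj, np.zeros(p), method="BFGS", options={"gtol": 1e-9, "maxiter": 500}
        )
        hess = _numeric_hessian(glm_obj, res.x)
        return ModelFit(
            family="binomial",
            species_levels=levels,
            beta=res.x.copy(),
            vcov_fixed=_safe_inv(hess),
            sigma_u2=0.0,
            sigma_e2=float("nan"),
            loglik=-float(res.fun),
            n_obs=n,
            n_groups=G,
            separation=separation,
        )

    obj = _LaplaceObjective(X, y, gidx, G, ridge=ridge)
    if fixed_sigma_u2 is not None:
        theta_fix = float(np.log(fixed_sigma_u2))

        def obj_beta(beta):
            return obj(np.append(beta, theta_fix))

        res = optimize.minimize(
            obj_beta, np.zeros(p), method="BFGS", options={"gtol": 1e-7, "maxiter": 500}
        )
        params = np.append(res.x, theta_fix)
        hess = _numeric_hessian(obj_beta, res.x)
        return ModelFit(
            family="binomial",
            species_levels=levels,
            beta=res.x.copy(),
            vcov_fixed=_safe_inv(hess),
            sigma_u2=fixed_sigma_u2,
            sigma_e2=float("nan"),
            loglik=-float(res.fun),
            n_obs=n,
            n_groups=G,
            separation=separation,
        )

    x0 = np.zeros(p + 1)  # beta = 0, log sigma_u^2 = 0
    res = optimize.minimize(
        obj,
        x0,
        method="BFGS",
        options={"gtol": 1e-7, "maxiter": 500},
    )
    params = res.x
    sigma_u2 = float(np.exp(params[-1]))
    # variance at (near-)zero boundary: clamp tiny estimates to zero
    if sigma_u2 < 1e-8:
        sigma_u2 = 0.0

    hess = _numeric_hessian(obj, params)
    vcov_full = _safe_inv(hess)
    vcov = vcov_full[:p, :p]
    return ModelFit(
        family="binomial",
        species_levels=levels,
        beta=params[:p].copy(),
        vcov_fixed=vcov,
        sigma_u2=sigma_u2,
        sigma_e2=float("nan"),
        loglik=-float(res.fun),
        n_obs=n,
        n_groups=G,
        separation=separation,
    )


def _numeric_hessian(f, x, h=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            fij = f(x + ei + ej)
            fi = f(x + ei)
            fj = f(x + ej)
            H[i, j] = H[j, i] = (fij - fi - fj + f0) / (h * h)
    return H


def _safe_inv(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


# ---------------------------------------------------------------------------
# LS-means


def ls_means(fit: ModelFit) -> LSMeans:
    """Marginal species means at random effect zero, with Wald SEs.

    With a species-only fixed structure the LS-mean of species s is the
    intercept plus its reference-coded effect; for the binomial family a
    logistic-transformed probability is reported alongside the log-odds.
    """
    k = len(fit.species_levels)
    C = np.zeros((k, k))
    C[:, 0] = 1.0
    for i in range(1, k):
        C[i, i] = 1.0
    est = C @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, fit.vcov_fixed, C), 0.0))
    prob = special.expit(est) if fit.family == "binomial" else None
    return LSMeans(
        species=list(fit.species_levels), estimate=est, se=se, probability=prob
    )


# ---------------------------------------------------------------------------
# Shaffer S1 step-down over all pairwise contrasts


def _partitions(n: int):
    """Integer partitions of n (as tuples, descending)."""
    if n == 0:
        yield ()
        return
    for first in range(n, 0, -1):
        for rest in _partitions(n - first):
            if not rest or rest[0] <= first:
                yield (first,) + rest


def shaffer_attainable(k: int) -> set[int]:
    """Attainable numbers of true pairwise-equality hypotheses among k means.

    Any configuration of equalities among k means is a set partition; a
    block of size b contributes C(b, 2) true hypotheses. Only the block
    sizes matter, so integer partitions of k suffice.
    """
    return {sum(b * (b - 1) // 2 for b in part) for part in _partitions(k)}


def shaffer_multipliers(k: int) -> list[int]:
    """Step-down multiplier at each step i (p ascending), i = 1..C(k,2).

    At step i the multiplier is the largest attainable count of true
    hypotheses that is still <= m - i + 1.
    """
    m = k * (k - 1) // 2
    attain = shaffer_attainable(k)
    mult = []
    for i in range(1, m + 1):
        cap = m - i + 1
        mult.append(max(a for a in attain if a <= cap))
    return mult


def shaffer_adjust(p_raw: np.ndarray, k: int) -> np.ndarray:
    """Shaffer S1 adjusted p-values for all C(k,2) pairwise tests."""
    p = np.asarray(p_raw, dtype=float)
    m = k * (k - 1) // 2
    if len(p) != m:
        raise InferenceError(f"expected {m} pairwise p-values, got {len(p)}")
    order = np.argsort(p, kind="stable")
    mult = np.array(shaffer_multipliers(k), dtype=float)
    adj_sorted = np.minimum.accumulate((mult * p[order])[::-1])[::-1]
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty_like(p)
    out[order] = adj_sorted
    return out


def tukey_shaffer(fit: ModelFit) -> list[PairwiseContrast]:
    """All pairwise species contrasts with Shaffer-corrected p-values.

    z statistics use Wald SEs from the fixed-effect covariance and a
    standard-normal reference (the asymptotic convention for mixed-model
    contrasts); multiplicity correction is the Shaffer S1 step-down.
    """
    k = len(fit.species_levels)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    contrasts = []
    for i, j in pairs:
        c = np.zeros(k)
        # lsmean difference: (mu + b_i) - (mu + b_j) = b_i - b_j
        if i > 0:
            c[i] = 1.0
        if j > 0:
            c[j] -= 1.0
        est = float(c @ fit.beta)
        se = float(np.sqrt(max(c @ fit.vcov_fixed @ c, 0.0)))
        z = est / se if se > 0 else np.inf * np.sign(est)
        p = 2.0 * norm.sf(abs(z))
        contrasts.append(
            PairwiseContrast(
                species_a=fit.species_levels[i],
                species_b=fit.species_levels[j],
                estimate=est,
                se=se,
                z=z,
                p_raw=float(p),
            )
        )
    p_adj = shaffer_adjust(np.array([c.p_raw for c in contrasts]), k)
    for c, pa in zip(contrasts, p_adj):
        c.p_adjusted = float(pa)
    return contrasts


def holm_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Holm step-down (used as a dominance reference, not in the pipeline)."""
    p = np.asarray(p_raw, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    mult = np.arange(m, 0, -1, dtype=float)
    adj_sorted = np.maximum.accumulate(np.minimum(mult * p[order], 1.0))
    out = np.empty_like(p)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# Species inclusion rule


def species_inclusion(category_df: pd.DataFrame, min_subplots: int = 3) -> set[str]:
    """Species present in at least ``min_subplots`` distinct subplots.

    The rule counts subplots, not seedlings: ten seedlings crowded into
    two subplots do not qualify.
    """
    if len(category_df) == 0:
        return set()
    counts = category_df.groupby("species")["subplot_id"].nunique()
    return set(counts[counts >= min_subplots].index)


# ---------------------------------------------------------------------------
# Per-(category, metric) driver


def fit_category_metric(
    data: pd.DataFrame,
    metric: str,
    min_subplots: int = 3,
) -> tuple[ModelFit, LSMeans, list[PairwiseContrast], set[str]] | None:
    """Inclusion-filter, fit, LS-means, and contrasts for one cell.

    ``data`` holds one row per seedling with ``species``, ``subplot_id``
    and the metric column; rows with undefined metric are dropped first.
    Returns None when fewer than two species survive the filters.
    """
    sub = data.dropna(subset=[metric])
    included = species_inclusion(sub, min_subplots=min_subplots)
    sub = sub[sub["species"].isin(included)]
    if len(included) < 2 or len(sub) == 0:
        return None
    y = sub[metric].to_numpy(dtype=float)
    if metric == "survival":
        if len(set(y.tolist())) < 2:
            return None
        fit = fit_binomial_glmm(y, sub["species"].to_numpy(), sub["subplot_id"].to_numpy())
    else:
        if sub["subplot_id"].nunique() < 2 or len(sub) <= len(included):
            return None
        fit = fit_gaussian_lmm(y, sub["species"].to_numpy(), sub["subplot_id"].to_numpy())
    lsm = ls_means(fit)
    contrasts = tukey_shaffer(fit)
    return fit, lsm, contrasts, included
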