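"""Independent reference implementations used only as test oracles.

These deliberately use naive dense-matrix / enumeration / quadrature
routes so they share no code path with the package implementation.
"""

import itertools
import math

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, special


def build_species_design(species):
    levels = sorted(set(species))
    X = np.ones((len(species), len(levels)))
    for k, lv in enumerate(levels[1:], start=1):
        X[:, k] = (np.asarray(species) == lv).astype(float)
    return X, levels


def dense_gls_reml(y, species, subplot, n_grid=200):
    """Gaussian random-intercept REML by dense-matrix GLS with the
    variance ratio grid-searched, then refined by golden-section."""
    y = np.asarray(y, dtype=float)
    X, levels = build_species_design(species)
    glabels, gidx = np.unique(subplot, return_inverse=True)
    n, p = X.shape
    Z = np.zeros((n, len(glabels)))
    Z[np.arange(n), gidx] = 1.0

    def neg_reml(lam):
        V = np.eye(n) + lam * Z @ Z.T
        Vi = np.linalg.inv(V)
        XtVX = X.T @ Vi @ X
        beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
        r = y - X @ beta
        rss = float(r @ Vi @ r)
        _, ld_v = np.linalg.slogdet(V)
        _, ld_x = np.linalg.slogdet(XtVX)
        return (n - p) * math.log(rss) + ld_v + ld_x

    lams = np.concatenate([[0.0], np.exp(np.linspace(-12, 8, n_grid - 1))])
    vals = [neg_reml(l) for l in lams]
    k = int(np.argmin(vals))
    lam = lams[k]
    if 0 < k < len(lams) - 1:
        res = optimize.minimize_scalar(
            neg_reml, bounds=(lams[k - 1], lams[k + 1]), method="bounded",
            options={"xatol": 1e-12},
        )
        if res.fun < vals[k]:
            lam = float(res.x)
    V = np.eye(n) + lam * Z @ Z.T
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    r = y - X @ beta
    sigma_e2 = float(r @ Vi @ r) / (n - p)
    vcov = sigma_e2 * np.linalg.inv(XtVX)
    return beta, vcov, lam * sigma_e2, sigma_e2, levels


def glmm_exact_nll(beta, sigma2, X, y, gidx, n_groups, nodes=40):
    """Exact logistic random-intercept marginal likelihood by adaptive
    Gauss-Hermite quadrature of each subplot's integral."""
    sigma = math.sqrt(sigma2)
    z, w = hermegauss(nodes)
    eta_f = X @ beta
    total = 0.0
    for g in range(n_groups):
        m = gidx == g
        yg, ef = y[m], eta_f[m]
        u = 0.0
        for _ in range(60):
            p = special.expit(ef + u)
            g1 = np.sum(yg - p) - u / sigma2
            h = -np.sum(p * (1 - p)) - 1.0 / sigma2
            step = g1 / h
            u -= step
            if abs(step) < 1e-13:
                break
        p = special.expit(ef + u)
        s = 1.0 / math.sqrt(np.sum(p * (1 - p)) + 1.0 / sigma2)
        uu = u + s * z
        ll = (
            yg[:, None] * (ef[:, None] + uu[None, :])
            - np.logaddexp(0.0, ef[:, None] + uu[None, :])
        ).sum(axis=0)
        ll = ll - 0.5 * uu**2 / sigma2
        logint = (
            ll + 0.5 * z**2 + np.log(w) + math.log(s) - math.log(sigma)
            - 0.5 * math.log(2.0 * math.pi)
        )
        mx = logint.max()
        total += mx + math.log(np.sum(np.exp(logint - mx)))
    return -total


def glmm_exact_beta_mle(y, species, subplot, sigma2, beta0=None):
    """Fixed effects maximizing the exact marginal likelihood at known
    random-intercept variance."""
    y = np.asarray(y, dtype=float)
    X, levels = build_species_design(species)
    glabels, gidx = np.unique(subplot, return_inverse=True)
    x0 = np.zeros(X.shape[1]) if beta0 is None else np.asarray(beta0)
    res = optimize.minimize(
        lambda b: glmm_exact_nll(b, sigma2, X, y, gidx, len(glabels)),
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 5000},
    )
    return res.x, levels


def set_partitions(items):
    """All set partitions of a list (restricted growth strings)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def shaffer_multipliers_bruteforce(k):
    """Shaffer step multipliers from explicit set-partition enumeration."""
    attain = set()
    for part in set_partitions(list(range(k))):
        attain.add(sum(len(b) * (len(b) - 1) // 2 for b in part))
    m = k * (k - 1) // 2
    return [max(a for a in attain if a <= m - i + 1) for i in range(1, m + 1)]


def lmg_bruteforce(y, covariate, blocks):
    """LMG shares by explicit enumeration of all block orderings."""
    names = sorted(blocks)
    y = np.asarray(y, dtype=float)
    n = len(y)

    def r2(subset):
        cols = [np.ones(n)]
        if covariate is not None:
            cols.append(np.asarray(covariate, dtype=float))
        for b in subset:
            cols.append(blocks[b])
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sst = np.sum((y - y.mean()) ** 2)
        return 1.0 - float(resid @ resid) / sst

    shares = {b: 0.0 for b in names}
    orders = list(itertools.permutations(names))
    for order in orders:
        so_far = []
        prev = r2(so_far)
        for b in order:
            so_far.append(b)
            cur = r2(so_far)
            shares[b] += cur - prev
            prev = cur
    return {b: s / len(orders) for b, s in shares.items()}
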