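"""Shared numerical routines.

This module collects the statistical workhorses used by the scoring and
differential-state machinery:

* a tricube-weighted local-polynomial smoother (mean-variance and
  mean-dispersion trends),
* empirical-Bayes variance shrinkage by moment matching on log variances
  (digamma/trigamma inversion),
* random-intercept variance components for models of the form
  ``y ~ (1|f1) + (1|f2) + ...`` with categorical factors, estimated either by
  a Henderson-style method of moments (closed form, vectorized across genes)
  or by profiled REML on collapsed sufficient statistics,
* negative-binomial GLM fitting (vectorized IRLS), Cox-Reid-style adjusted
  profile-likelihood dispersion estimation with trend shrinkage, and an
  EB-moderated quasi-likelihood F-test for a group contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats


# --------------------------------------------------------------------------
# local regression
# --------------------------------------------------------------------------

def loess_fit(x, y, frac: float = 0.3, degree: int = 2) -> np.ndarray:
    """Fitted values of a tricube-weighted local polynomial of ``y`` on ``x``.

    Exact ties in ``x`` are allowed; each point is fitted from the
    ``ceil(frac * n)`` nearest neighbours in ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if np.unique(x).size < 3:
        raise ValueError("trend unfittable: fewer than 3 distinct x values")
    k = int(np.ceil(frac * n))
    k = min(n, max(k, degree + 2))
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    fitted = np.empty(n)
    for i in range(n):
        xi = x[i]
        pos = int(np.searchsorted(xs, xi))
        lo, hi = max(0, pos - k), min(n, pos + k)
        xw, yw = xs[lo:hi], ys[lo:hi]
        d = np.abs(xw - xi)
        if xw.size > k:
            sel = np.argpartition(d, k - 1)[:k]
            xw, yw, d = xw[sel], yw[sel], d[sel]
        dmax = d.max()
        w = np.ones_like(d) if dmax <= 0 else (1.0 - (d / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-12)
        X = np.vander(xw - xi, degree + 1, increasing=True)
        WX = X * w[:, None]
        A = WX.T @ X
        b = WX.T @ yw
        try:
            beta = np.linalg.solve(A + 1e-12 * np.eye(degree + 1), b)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(A, b, rcond=None)
        fitted[i] = beta[0]
    return fitted


# --------------------------------------------------------------------------
# empirical-Bayes variance shrinkage
# --------------------------------------------------------------------------

_D0_CAP = 1e6


def trigamma_inverse(x: float) -> float:
    """Solve ``trigamma(y) = x`` for ``y > 0`` (Newton on the inverse scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(80):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * abs(y):
            break
    return float(y)


def squeeze_var(s2, df, d0=None):
    """Shrink per-gene residual variances toward a common prior.

    Hyperparameters ``(d0, s0^2)`` are estimated by matching the first two
    moments of ``log s^2`` against the scaled-F sampling distribution.
    Passing ``d0=0`` disables shrinkage (classical variances); ``d0`` at or
    above 1e6 is treated as complete shrinkage to ``s0^2``.

    Returns ``(s2_post, d0, s0_2)``.
    """
    s2 = np.asarray(s2, dtype=float)
    df = float(df)
    ok = np.isfinite(s2) & (s2 > 0)
    s0_2 = None
    if d0 is None:
        if ok.sum() < 2:
            d0 = 0.0
        else:
            z = np.log(s2[ok])
            e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
            emean = float(np.mean(e))
            evar = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
            target = evar - float(special.polygamma(1, df / 2.0))
            if target <= 0:
                d0 = _D0_CAP
                s0_2 = float(np.exp(emean))
            else:
                d0 = min(2.0 * trigamma_inverse(target), _D0_CAP)
                s0_2 = float(
                    np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
                )
    if d0 == 0:
        return s2.copy(), 0.0, float(np.nan)
    if s0_2 is None:  # d0 supplied by caller without hyperparameter fit
        s0_2 = (
            float(np.exp(np.mean(np.log(s2[ok])))) if ok.any() else 1.0
        )
    if d0 >= _D0_CAP:
        return np.full_like(s2, s0_2), float(d0), s0_2
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, float(d0), s0_2


# --------------------------------------------------------------------------
# random-intercept variance components
# --------------------------------------------------------------------------

def _collapse(Y: np.ndarray, factors):
    """Collapse cells sharing a factor combination into sufficient statistics.

    Returns (ybar genes x J, nj, ssw per gene, combo level codes per factor).
    """
    Y = np.asarray(Y, dtype=float)
    keys = pd.MultiIndex.from_arrays([np.asarray(f) for f in factors])
    codes, uniques = pd.factorize(keys, sort=True)
    J = len(uniques)
    ind = np.zeros((Y.shape[1], J))
    ind[np.arange(Y.shape[1]), codes] = 1.0
    nj = ind.sum(axis=0)
    ybar = (Y @ ind) / nj
    sumsq = (Y**2) @ ind
    ssw = (sumsq - nj * ybar**2).sum(axis=1)
    if len(factors) == 1:
        level_codes = [np.asarray(pd.factorize(uniques, sort=True)[0])]
    else:
        level_codes = [
            np.asarray(pd.factorize(uniques.get_level_values(i), sort=True)[0])
            for i in range(len(factors))
        ]
    return ybar, nj, np.maximum(ssw, 0.0), level_codes


def _dummies(codes: np.ndarray) -> np.ndarray:
    L = int(codes.max()) + 1
    Z = np.zeros((codes.size, L))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def variance_components_mom(Y: np.ndarray, factors, factor_names=None) -> pd.DataFrame:
    """Henderson-style method-of-moments variance components, per gene.

    ``Y`` is genes x cells; ``factors`` a list of per-cell label vectors.
    Returns a DataFrame with one variance column per factor plus
    ``residual``; negative solutions are truncated at zero.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n_cells = Y.shape[1]
    F = len(factors)
    names = factor_names or [f"f{i}" for i in range(F)]
    ybar, nj, ssw, level_codes = _collapse(Y, factors)
    Z = [_dummies(c) for c in level_codes]  # combo-level incidence
    one = np.ones((len(nj), 1))

    def proj(Xc):
        XtWX = Xc.T @ (Xc * nj[:, None])
        G = np.linalg.pinv(XtWX)
        H = Xc @ G @ (Xc * nj[:, None]).T  # J x J
        rank = np.linalg.matrix_rank(np.sqrt(nj)[:, None] * Xc)
        return H, G, rank

    def ss_model(H):
        fitted = ybar @ H.T
        return ((fitted**2) * nj).sum(axis=1)

    def tr_PM(Xc, G, Zg):
        A = Xc.T @ (Zg * nj[:, None])  # p x L
        return float(np.trace(G @ A @ A.T))

    H1, G1, r1 = proj(one)
    ss1 = ss_model(H1)
    X_full = np.hstack([one] + Z)
    Hf, Gf, rf = proj(X_full)
    tot = ssw + (nj * ybar**2).sum(axis=1)
    rss_full = np.maximum(tot - ss_model(Hf), 0.0)
    df_resid = n_cells - rf
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom for variance components")
    sig_e = rss_full / df_resid

    q = np.empty((F, Y.shape[0]))
    T = np.empty((F, F))
    trA = np.empty(F)
    for i in range(F):
        Xi = np.hstack([one, Z[i]])
        Hi, Gi, ri = proj(Xi)
        q[i] = ss_model(Hi) - ss1
        trA[i] = ri - r1
        for g in range(F):
            T[i, g] = tr_PM(Xi, Gi, Z[g]) - tr_PM(one, G1, Z[g])
    rhs = q - trA[:, None] * sig_e[None, :]
    sol, *_ = np.linalg.lstsq(T, rhs, rcond=None)
    sol = np.maximum(sol, 0.0)
    out = pd.DataFrame({names[i]: sol[i] for i in range(F)})
    out["residual"] = sig_e
    return out


def _reml_neg2ll_grad(log_gamma, ybar_g, nj, ssw_g, M, n_cells):
    """Profiled REML -2 log-likelihood and gradient in log-ratio coordinates.

    ``M`` is the list of combo-level Z_f Z_f' matrices; the residual variance
    is profiled out using both the between-combo quadratic form and the
    pooled within-combo sum of squares.
    """
    J = nj.size
    gam = np.exp(log_gamma)
    W = np.diag(1.0 / nj)
    for gm, Mf in zip(gam, M):
        W = W + gm * Mf
    try:
        Winv = np.linalg.inv(W)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros_like(log_gamma)
    one = np.ones(J)
    wi1 = Winv @ one
    xwx = float(one @ wi1)
    P = Winv - np.outer(wi1, wi1) / xwx
    Py = P @ ybar_g
    quad = float(ybar_g @ Py) + ssw_g
    sig_e = max(quad / (n_cells - 1), 1e-300)
    sign, logdetW = np.linalg.slogdet(W)
    if sign <= 0:
        return 1e12, np.zeros_like(log_gamma)
    val = logdetW + np.log(xwx) + (n_cells - 1) * np.log(sig_e)
    grad = np.empty_like(log_gamma)
    for i, Mf in enumerate(M):
        tr_pm = float(np.sum(P * Mf))  # tr(P M), M symmetric
        qf = float(Py @ Mf @ Py)
        grad[i] = gam[i] * (tr_pm - qf / sig_e)
    return val, grad


def variance_components_reml(Y, factors, factor_names=None, max_iter=200) -> pd.DataFrame:
    """Profiled-REML variance components (per-gene quasi-Newton on collapsed
    sufficient statistics, analytic gradient, MoM warm starts).

    Same return layout as :func:`variance_components_mom`.
    """
    from scipy.optimize import minimize

    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n_cells = Y.shape[1]
    F = len(factors)
    names = factor_names or [f"f{i}" for i in range(F)]
    ybar, nj, ssw, level_codes = _collapse(Y, factors)
    Z = [_dummies(c) for c in level_codes]
    M = [Zf @ Zf.T for Zf in Z]
    # warm start from the method-of-moments solution
    mom = variance_components_mom(Y, factors, names)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mom[names].to_numpy() / mom["residual"].to_numpy()[:, None]
    x0_all = np.log(np.clip(np.nan_to_num(ratio, nan=0.3, posinf=10.0), 1e-4, 1e4))
    rows = []
    for g in range(Y.shape[0]):
        yg = ybar[g]
        if np.var(yg) < 1e-14 and ssw[g] < 1e-14:
            rows.append([0.0] * F + [0.0])
            continue
        res = minimize(
            _reml_neg2ll_grad,
            x0=x0_all[g],
            args=(yg, nj, ssw[g], M, n_cells),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-23.0, 12.0)] * F,
            options={"maxiter": max_iter, "ftol": 1e-10},
        )
        gam = np.exp(res.x)
        W = np.diag(1.0 / nj)
        for gm, Mf in zip(gam, M):
            W = W + gm * Mf
        Winv = np.linalg.inv(W)
        one = np.ones(nj.size)
        wi1 = Winv @ one
        xwx = float(one @ wi1)
        P = Winv - np.outer(wi1, wi1) / xwx
        sig_e = (float(yg @ P @ yg) + ssw[g]) / (n_cells - 1)
        var_f = gam * sig_e
        var_f[var_f < 1e-8 * max(sig_e, 1e-12)] = 0.0
        rows.append(list(var_f) + [sig_e])
    out = pd.DataFrame(rows, columns=names + ["residual"])
    return out


def variance_components(Y, factors, factor_names=None, method="mom") -> pd.DataFrame:
    if method == "mom":
        return variance_components_mom(Y, factors, factor_names)
    if method == "reml":
        return variance_components_reml(Y, factors, factor_names)
    raise ValueError(f"unknown variance-component method: {method!r}")


# --------------------------------------------------------------------------
# negative-binomial GLM machinery
# --------------------------------------------------------------------------

def nb_deviance(y, mu, alpha):
    """Per-observation NB deviance; Poisson limit for tiny dispersion."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim == 1:
        alpha = alpha[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(np.maximum(y, 1e-12) / mu), 0.0)
        small = alpha < 1e-10
        a = np.where(small, 1e-10, alpha)
        t2_nb = (y + 1.0 / a) * (np.log1p(a * y) - np.log1p(a * mu))
        t2 = np.where(small, y - mu, t2_nb)
    return 2.0 * (t1 - t2)


def nb_loglik(y, mu, alpha):
    """NB log-likelihood per observation (alpha floored at 1e-8)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    alpha = np.maximum(np.asarray(alpha, dtype=float), 1e-8)
    if alpha.ndim == 1:
        alpha = alpha[:, None]
    r = 1.0 / alpha
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + y * np.log(alpha * mu)
        - (y + r) * np.log1p(alpha * mu)
    )


def nb_fit(y, X, offset, alpha, n_iter=50, tol=1e-8):
    """Vectorized IRLS fit of per-gene NB GLMs with log link.

    ``y``: genes x units; ``X``: units x p; ``offset``: log library sizes;
    ``alpha``: per-gene (or scalar) dispersion. Returns (beta, mu, deviance).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    X = np.asarray(X, dtype=float)
    offset = np.asarray(offset, dtype=float)
    G, n = y.shape
    p = X.shape[1]
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (G,)).copy()
    mu = y + np.maximum(y.mean(axis=1, keepdims=True), 0.1)
    eta = np.log(mu)
    dev = nb_deviance(y, mu, alpha).sum(axis=1)
    ridge = 1e-8 * np.eye(p)
    for _ in range(n_iter):
        W = mu / (1.0 + alpha[:, None] * mu)
        W = np.maximum(W, 1e-12)
        z = (eta - offset[None, :]) + (y - mu) / mu
        XtWX = np.einsum("gn,ni,nj->gij", W, X, X) + ridge
        XtWz = np.einsum("gn,ni,gn->gi", W, X, z)
        beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        dev_new = nb_deviance(y, mu, alpha).sum(axis=1)
        if np.max(np.abs(dev_new - dev) / (np.abs(dev) + 1.0)) < tol:
            dev = dev_new
            break
        dev = dev_new
    return beta, mu, dev


def estimate_dispersion(y, X, offset, grid=None, span=0.5):
    """Per-gene NB dispersion via Cox-Reid adjusted profile likelihood.

    Maximized over a log-spaced grid; gene-wise estimates are then shrunk
    50/50 (in log space) toward a local-linear trend on log mean abundance.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    X = np.asarray(X, dtype=float)
    offset = np.asarray(offset, dtype=float)
    if grid is None:
        grid = np.logspace(-4, 1.3, 20)
    G = y.shape[0]
    apl = np.full((len(grid), G), -np.inf)
    nonzero = y.sum(axis=1) > 0
    for gi, a in enumerate(grid):
        beta, mu, _ = nb_fit(y, X, offset, a)
        W = mu / (1.0 + a * mu)
        XtWX = np.einsum("gn,ni,nj->gij", W, X, X) + 1e-8 * np.eye(X.shape[1])
        sign, logdet = np.linalg.slogdet(XtWX)
        ll = nb_loglik(y, mu, np.full(G, a)).sum(axis=1)
        apl[gi] = ll - 0.5 * logdet
    best = grid[np.argmax(apl, axis=0)]
    abund = np.log(y.mean(axis=1) / np.exp(offset).mean() + 1e-8)
    disp = best.copy()
    if nonzero.sum() >= 3 and np.unique(abund[nonzero]).size >= 3:
        trend = loess_fit(abund[nonzero], np.log(best[nonzero]), frac=span, degree=1)
        disp[nonzero] = np.exp(0.5 * np.log(best[nonzero]) + 0.5 * trend)
    disp = np.clip(disp, grid[0], grid[-1])
    disp[~nonzero] = np.median(disp[nonzero]) if nonzero.any() else grid[0]
    return disp


def ql_group_test(y, X_full, X_null, offset, alpha=None):
    """Quasi-likelihood F-test of the terms in ``X_full`` beyond ``X_null``.

    Residual deviance dispersions are EB-squeezed across genes; the test
    statistic is the deviance difference divided by (df_test x squeezed
    quasi-dispersion), referred to F(df_test, d0 + df_resid).

    Returns a dict with p, F, beta (full fit), dispersion, df_resid, d0.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n = y.shape[1]
    r_full = np.linalg.matrix_rank(X_full)
    r_null = np.linalg.matrix_rank(X_null)
    df_test = r_full - r_null
    df_resid = n - r_full
    if df_test < 1:
        raise ValueError("full design adds no testable coefficients")
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom; more replicates needed")
    if alpha is None:
        alpha = estimate_dispersion(y, X_full, offset)
    beta, mu, dev_full = nb_fit(y, X_full, offset, alpha)
    _, _, dev_null = nb_fit(y, X_null, offset, alpha)
    nonzero = y.sum(axis=1) > 0
    s2 = dev_full / df_resid
    post = np.full(y.shape[0], np.nan)
    d0 = 0.0
    if nonzero.any():
        s2_post, d0, _ = squeeze_var(np.maximum(s2[nonzero], 1e-10), df_resid)
        post[nonzero] = s2_post
    F = np.zeros(y.shape[0])
    delta = np.maximum(dev_null - dev_full, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F[nonzero] = delta[nonzero] / (df_test * np.maximum(post[nonzero], 1e-10))
    df2 = min(d0, _D0_CAP) + df_resid if d0 > 0 else float(df_resid)
    pvals = np.ones(y.shape[0])
    pvals[nonzero] = stats.f.sf(F[nonzero], df_test, df2)
    return {
        "p": pvals,
        "F": F,
        "beta": beta,
        "dispersion": np.broadcast_to(alpha, (y.shape[0],)),
        "df_resid": df_resid,
        "df_test": df_test,
        "d0": d0,
        "tested": nonzero,
    }


def bh_adjust(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]
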