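"""Independent oracles used by the test suite.

These implementations deliberately avoid the package's computational routes:
the restricted log-likelihood is assembled record by record with explicit
loops and generic dense linear algebra, and the maximization uses
derivative-free simplex search with multiple starts plus a numeric-gradient
polish.  Slow, but trustworthy on tiny instances.
"""

import numpy as np
from scipy import optimize

from tetrablup.io_tables import TIME_POINTS
from tetrablup.traits import average_reps


def design_arrays(pheno, grm, trait, times):
    """Raw y, X, and index arrays for a one-trait record set (no checks)."""
    df = average_reps(pheno.filter(trait=trait, time_points=times)).df
    df = df.dropna(subset=["value"]).reset_index(drop=True)
    assert not df["is_check"].any(), "oracle helper assumes no check genotypes"
    gl = [g for g in grm.genotype_ids if g in set(df["genotype"])]
    gpos = {g: i for i, g in enumerate(gl)}
    tpos = {t: i for i, t in enumerate(times)}
    y = df["value"].to_numpy(float)
    gidx = np.array([gpos[g] for g in df["genotype"]])
    tidx = np.array([tpos[str(t)] for t in df["time_point"]])
    units = {key: i for i, key in enumerate(dict.fromkeys(zip(df["genotype"], df["year"])))}
    uidx = np.array([units[k] for k in zip(df["genotype"], df["year"])])
    X = np.zeros((len(y), len(times)))
    X[np.arange(len(y)), tidx] = 1.0
    years = sorted(df["year"].unique())
    for yr in years[1:]:
        X = np.column_stack([X, (df["year"] == yr).to_numpy(float)])
    G = grm.submatrix(gl)
    return y, X, G, gidx, tidx, uidx


def naive_reml_loglik(y, X, G, St, Se, gidx, tidx, uidx):
    """REML log-likelihood from the covariance definition.

    V is assembled directly from the model definition (genetic covariance
    G_ik * St_ts between any two records, residual Se_ts within a harvest
    unit) and evaluated with generic slogdet/inv algebra — no Cholesky
    identities, rotations, or gradients shared with the package engine.
    """
    V = G[np.ix_(gidx, gidx)] * St[np.ix_(tidx, tidx)]
    V = V + (uidx[:, None] == uidx[None, :]) * Se[np.ix_(tidx, tidx)]
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    sign_a, logdetA = np.linalg.slogdet(A)
    if sign_a <= 0:
        return -np.inf
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    quad = r @ Vi @ r
    n, p = X.shape
    return -0.5 * (logdetV + logdetA + quad + (n - p) * np.log(2 * np.pi))


def _theta_to_cov(theta, T):
    """Two log-Cholesky factors packed into one vector."""
    k = T * (T + 1) // 2

    def build(vec):
        L = np.zeros((T, T))
        m = 0
        for i in range(T):
            for j in range(i + 1):
                L[i, j] = np.exp(vec[m]) if i == j else vec[m]
                m += 1
        return L @ L.T

    return build(theta[:k]), build(theta[k:])


def _cov_to_theta(St, Se):
    out = []
    for S in (St, Se):
        T = S.shape[0]
        L = np.linalg.cholesky(S + 1e-8 * np.eye(T))
        for i in range(T):
            for j in range(i + 1):
                out.append(np.log(max(L[i, i], 1e-6)) if i == j else L[i, j])
    return np.array(out)


def brute_force_reml(y, X, G, gidx, tidx, uidx, T):
    """Maximize the naive restricted likelihood by multi-start simplex search.

    Returns the best log-likelihood found.  Intended for T = 2 and a few
    dozen records, where the 6-parameter surface is easy to search.
    """

    def negll(theta):
        St, Se = _theta_to_cov(theta, T)
        ll = naive_reml_loglik(y, X, G, St, Se, gidx, tidx, uidx)
        return -ll if np.isfinite(ll) else 1e12

    # moment starts: split the sample covariance in different proportions
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    units = np.unique(uidx)
    mat = np.full((len(units), T), np.nan)
    for u, t, v in zip(uidx, tidx, resid):
        mat[np.searchsorted(units, u), t] = v
    S = np.ma.cov(np.ma.masked_invalid(mat), rowvar=False).filled(0.0)
    S = S + 1e-3 * np.trace(S) / T * np.eye(T)
    md = float(np.mean(np.diag(G[np.unique(gidx)][:, np.unique(gidx)])))

    # moment-split starts plus near-rank-1 genetic starts: data without a
    # genotype-by-time interaction push the genetic correlation to 1, a
    # boundary basin a generic moment start can miss
    starts = [
        _cov_to_theta(wg * S / md, (1 - wg) * S) for wg in (0.5, 0.2, 0.8, 0.05, 0.95)
    ]
    vbar = float(np.mean(np.diag(S)))
    rank1 = vbar * (np.full((T, T), 0.999) + 0.001 * np.eye(T))
    starts += [
        _cov_to_theta(wg * rank1 / md, (1 - wg) * S) for wg in (0.5, 0.9)
    ]
    best = np.inf
    best_x = None
    for x0 in starts:
        res = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if res.fun < best:
            best, best_x = res.fun, res.x
    # perturbation restarts: simplex search can stall in the curved valleys
    # that near-singular covariances create in Cholesky coordinates
    rng = np.random.default_rng(12345)
    for scale in (0.5, 0.5, 0.2, 0.2, 0.05, 0.05):
        x0 = best_x + rng.normal(0.0, scale, size=best_x.size)
        res = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if res.fun < best:
            best, best_x = res.fun, res.x
    # alternate simplex and direction-set polishes until no further gain
    for _ in range(4):
        gained = False
        for method, opts in (
            ("Powell", {"maxiter": 4000, "xtol": 1e-10, "ftol": 1e-12}),
            ("Nelder-Mead", {"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-11}),
        ):
            res = optimize.minimize(negll, best_x, method=method, options=opts)
            if res.fun < best - 1e-10:
                gained = True
            if res.fun < best:
                best, best_x = res.fun, res.x
        if not gained:
            break
    return -best
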