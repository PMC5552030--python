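"""Stratified elevation regression with spatial residual correlation.

The community-elevation relationship is quantified by maximum likelihood for

    elevation_i = mu_{c(i)} + eps_i,
    Cov(eps_i, eps_j) = sigma_{c(i)} sigma_{c(j)} exp(-d_ij / r)   (i != j),
    Var(eps_i) = sigma_{c(i)}^2,

i.e. a per-community mean, a per-community residual SD ("stratum SD"), and
an exponential correlation in the pixel-to-pixel distance with range ``r``
(meters).  Means and the overall variance scale are profiled analytically;
the optimizer works on ``log r`` (outer, bounded scalar search — the
correlation Cholesky depends only on ``r``) and the log SD ratios (inner
quasi-Newton reusing that factorization), which keeps a dense-covariance
fit at n = 2,000 tractable.

Model fit is summarized by Nagelkerke's pseudo-R^2 against the
intercept-only iid null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.spatial.distance import pdist, squareform

from .errors import FitError, InputError
from .matrix import gaussian_kde_grid, silverman_bandwidth

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class StratifiedElevationFit:
    """Per-community elevation estimates plus spatial-correlation summary."""

    table: pd.DataFrame        # index community: mean, ci_lo, ci_hi, sd, n, identifiable
    range_m: float | None      # exponential correlation range (m); None if iid fit
    loglik: float
    loglik_null: float
    r2: float                  # Nagelkerke pseudo-R^2
    n: int
    correlation: str
    converged: bool = True
    nugget: float | None = None

    def __post_init__(self):
        ok = self.table["identifiable"]
        t = self.table.loc[ok]
        assert ((t["ci_lo"] <= t["mean"]) & (t["mean"] <= t["ci_hi"])).all()


def nagelkerke_r2(ll_fitted: float, ll_null: float, n: int) -> float:
    """Nagelkerke's pseudo-R^2 for a likelihood-ratio comparison.

    ``[1 - exp(2 (ll_null - ll_fitted)/n)] / [1 - exp(2 ll_null / n)]``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if ll_fitted < ll_null:
        warnings.warn("fitted log-likelihood below null", stacklevel=2)
    num = 1.0 - np.exp(2.0 * (ll_null - ll_fitted) / n)
    den = 1.0 - np.exp(2.0 * ll_null / n)
    if den == 0.0:
        return 0.0
    return float(num / den)


def _null_loglik(y: np.ndarray) -> float:
    n = y.size
    s2 = float(np.var(y))
    if s2 == 0.0:
        return np.inf
    return -0.5 * n * (_LOG2PI + np.log(s2) + 1.0)


def _fit_iid(y, codes, communities, n_per, z) -> StratifiedElevationFit:
    """Heteroscedastic stratified fit with independent errors (closed form)."""
    rows = []
    ll = 0.0
    pooled_ss = 0.0
    n = y.size
    for i, c in enumerate(communities):
        yi = y[codes == i]
        mu = float(yi.mean())
        if yi.size >= 2:
            sd = float(np.sqrt(np.mean((yi - mu) ** 2)))
            se = sd / np.sqrt(yi.size)
            ident = True
        else:
            sd, se, ident = np.nan, np.nan, False
        pooled_ss += float(((yi - mu) ** 2).sum())
        rows.append((c, mu, mu - z * se, mu + z * se, sd, yi.size, ident))
    pooled_sd = np.sqrt(pooled_ss / n)
    for c, mu, lo, hi, sd, ni, ident in rows:
        s = sd if (ident and sd > 0) else pooled_sd
        if not s > 0:  # degenerate (constant) stratum
            ll = np.inf
            continue
        yi = y[codes == communities.index(c)]
        ll += float(-0.5 * (ni * (_LOG2PI + 2 * np.log(s))
                            + ((yi - mu) ** 2).sum() / s**2))
    table = pd.DataFrame(
        rows, columns=["community", "mean", "ci_lo", "ci_hi", "sd", "n",
                       "identifiable"]
    ).set_index("community")
    ll_null = _null_loglik(y)
    return StratifiedElevationFit(
        table=table, range_m=None, loglik=ll, loglik_null=ll_null,
        r2=nagelkerke_r2(ll, ll_null, n) if np.isfinite(ll) else 1.0,
        n=n, correlation="none",
    )


def _chol_corr(D: np.ndarray, r: float, nugget: float):
    C = np.exp(-D / r)
    if nugget > 0.0:
        C *= (1.0 - nugget)
        np.fill_diagonal(C, 1.0)
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return np.linalg.cholesky(C + jitter * np.eye(C.shape[0]))
        except np.linalg.LinAlgError:
            continue
    raise FitError("correlation matrix not positive definite",
                   {"range": r, "nugget": nugget})


def _profiled_neg2ll(L, y, codes, k, gammas, n_per):
    """-2 log L with means and overall variance scale profiled out."""
    n = y.size
    g = gammas[codes]
    yg = y / g
    Xg = np.zeros((n, k))
    Xg[np.arange(n), codes] = 1.0 / g
    A = solve_triangular(L, np.column_stack([Xg, yg]), lower=True,
                         check_finite=False)
    Qx, qy = A[:, :-1], A[:, -1]
    XtX = Qx.T @ Qx
    try:
        cf = cho_factor(XtX)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular design in GLS profile", {"gammas": gammas}) from exc
    mu = cho_solve(cf, Qx.T @ qy)
    resid = qy - Qx @ mu
    Q = float(resid @ resid)
    logdetC = 2.0 * float(np.log(np.diag(L)).sum())
    glog = 2.0 * float(n_per @ np.log(gammas))
    neg2 = n * _LOG2PI + n * np.log(Q / n) + n + logdetC + glog
    return neg2, mu, Q, cf


def fit_stratified_gls(
    sample: pd.DataFrame,
    correlation: str = "exponential",
    nugget: bool = False,
    ci_level: float = 0.95,
    max_n: int = 10_000,
) -> StratifiedElevationFit:
    """ML fit of the stratified heteroscedastic (spatial) elevation model.

    Parameters
    ----------
    sample
        Pixel table with ``x``, ``y`` (projected meters), ``elevation`` and
        categorical ``community`` columns; only communities present are fit.
    correlation
        ``"exponential"`` for the spatial model, ``"none"`` for independent
        errors (the nested model; closed form).
    nugget
        Add a nugget (short-range discontinuity) to the correlation.
    max_n
        Guard on the dense-covariance cost; raise above this size.
    """
    n = len(sample)
    if n < 2:
        raise InputError("need at least 2 pixels")
    if n > max_n:
        raise InputError(f"n = {n} exceeds max_n = {max_n}; subsample first")
    y = sample["elevation"].to_numpy(dtype=float)
    cats = sample["community"]
    present = [c for c in cats.cat.categories if (cats == c).any()]
    codes = pd.Categorical(cats, categories=present).codes.astype(int)
    k = len(present)
    n_per = np.bincount(codes, minlength=k).astype(float)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)

    if correlation == "none":
        return _fit_iid(y, codes, present, n_per, z)
    if correlation != "exponential":
        raise InputError(f"unknown correlation {correlation!r}")

    coords = sample[["x", "y"]].to_numpy(dtype=float)
    d = pdist(coords)
    d_pos = d[d > 0]
    if d_pos.size == 0:
        raise FitError("all pixels share one location")
    D = squareform(d)
    log_r_lo = np.log(max(d_pos.min() / 5.0, 1e-6))
    log_r_hi = np.log(d.max() * 5.0)

    # start at the iid estimates
    iid = _fit_iid(y, codes, present, n_per, z)
    sd0 = iid.table["sd"].to_numpy(dtype=float)
    pooled = np.nanmean(sd0[sd0 > 0]) if np.any(sd0 > 0) else 1.0
    sd0 = np.where(np.isfinite(sd0) & (sd0 > 0), sd0, pooled)
    identifiable = iid.table["identifiable"].to_numpy() & (n_per >= 2)
    free = np.nonzero(identifiable)[0]
    anchor = free[0] if free.size else 0
    free = free[free != anchor]

    nug = 0.0  # optimized jointly with r when requested
    warm = {"theta": np.log(sd0[free] / sd0[anchor])}

    def gammas_from(theta):
        g = np.ones(k)
        g[free] = np.exp(theta)
        # unidentifiable strata pinned at the pooled ratio
        g[~identifiable] = pooled / sd0[anchor]
        return g * (sd0[anchor] / sd0[anchor])

    def inner(log_r, nugget_val, full=False):
        L = _chol_corr(D, float(np.exp(log_r)), nugget_val)

        def obj(theta):
            return _profiled_neg2ll(L, y, codes, k, gammas_from(theta),
                                    n_per)[0]

        if free.size:
            res = optimize.minimize(obj, warm["theta"], method="L-BFGS-B",
                                    options={"maxiter": 200})
            warm["theta"] = res.x
            theta = res.x
        else:
            theta = np.empty(0)
        g = gammas_from(theta)
        neg2, mu, Q, cf = _profiled_neg2ll(L, y, codes, k, g, n_per)
        if not full:
            return neg2
        tau2 = Q / n
        cov_mu = tau2 * cho_solve(cf, np.eye(k))
        return neg2, mu, np.sqrt(tau2) * g, np.sqrt(np.diag(cov_mu))

    if nugget:
        res2 = optimize.minimize(
            lambda p: inner(p[0], 1.0 / (1.0 + np.exp(-p[1]))),
            x0=[np.log(np.median(d_pos)), -2.0], method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 300},
        )
        best_log_r = res2.x[0]
        nug = 1.0 / (1.0 + np.exp(-res2.x[1]))
        converged = bool(res2.success)
    else:
        res1 = optimize.minimize_scalar(
            lambda lr: inner(lr, 0.0), bounds=(log_r_lo, log_r_hi),
            method="bounded", options={"xatol": 5e-3},
        )
        best_log_r = float(res1.x)
        converged = bool(res1.success)

    neg2, mu, sigmas, se = inner(best_log_r, nug, full=True)
    ll = -0.5 * neg2
    rows = []
    for i, c in enumerate(present):
        ident = bool(identifiable[i])
        rows.append((c, mu[i], mu[i] - z * se[i], mu[i] + z * se[i],
                     sigmas[i] if ident else np.nan, int(n_per[i]), ident))
    table = pd.DataFrame(
        rows, columns=["community", "mean", "ci_lo", "ci_hi", "sd", "n",
                       "identifiable"]
    ).set_index("community")
    ll_null = _null_loglik(y)
    return StratifiedElevationFit(
        table=table, range_m=float(np.exp(best_log_r)), loglik=ll,
        loglik_null=ll_null, r2=nagelkerke_r2(ll, ll_null, n), n=n,
        correlation="exponential", converged=converged,
        nugget=nug if nugget else None,
    )


def elevation_density_profiles(pixels: pd.DataFrame,
                               bandwidth="silverman",
                               n_grid: int = 512) -> pd.DataFrame:
    """Per-community elevation KDE curves on a shared axis.

    Returns a DataFrame with an ``elevation`` column plus one density column
    per community (communities with fewer than two pixels are skipped with a
    warning).  Each curve integrates to one over the padded axis.
    """
    cats = list(pixels["community"].cat.categories)
    groups = {c: pixels.loc[pixels["community"] == c, "elevation"].to_numpy()
              for c in cats}
    usable = [c for c in cats if groups[c].size >= 2]
    if not usable:
        raise InputError("no community has >= 2 pixels")
    for c in cats:
        if c not in usable:
            warnings.warn(f"community {c} has < 2 pixels; skipped",
                          stacklevel=2)
    bw = {
        c: (silverman_bandwidth(groups[c]) if bandwidth == "silverman"
            else float(bandwidth))
        for c in usable
    }
    pad = 3.0 * max(bw.values())
    e = np.concatenate([groups[c] for c in usable])
    grid = np.linspace(e.min() - pad, e.max() + pad, n_grid)
    out = pd.DataFrame({"elevation": grid})
    for c in usable:
        out[c] = gaussian_kde_grid(groups[c], grid, bw[c])
    return out
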