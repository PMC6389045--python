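"""Random-intercept linear mixed model estimated by REML.

Implements the model

    y_ij = x_ij' beta + mu_i + eps_ij,   mu_i ~ N(0, sigma2_mu),
                                         eps_ij ~ N(0, sigma2_eps),

for grouping factors with one or two observations per group (an individual
observed at up to two visits).  The variance components are estimated by
maximizing the restricted likelihood profiled over the variance ratio
lambda = sigma2_mu / sigma2_eps via a one-dimensional search on
log-lambda in [-12, 12]; the lambda -> 0 boundary (OLS) is checked
explicitly.  Fixed effects come from generalized least squares at the
optimum, and per-coefficient p-values use either a Satterthwaite
degrees-of-freedom approximation or a normal approximation.

The group structure makes every likelihood evaluation O(p^2): after an
orthogonal within-group transform (pair sum and difference), the
covariance is diagonal with weights 1/(1 + m*lambda) on group-mean rows
(m the group size) and 1 on contrast rows, so the weighted cross-products
decompose into three precomputed matrices combined per lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

_LOG_LAMBDA_BOUNDS = (-12.0, 12.0)
_BOUNDARY_LAMBDA = 1e-8


class _RIProblem:
    """Precomputed cross-products for a random-intercept problem."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        codes, counts = np.unique(groups, return_counts=True)
        if counts.max() > 2:
            raise ValueError("groups with more than two observations are not supported")
        code_of = {c: i for i, c in enumerate(codes)}
        gidx = np.fromiter((code_of[g] for g in groups), int, len(groups))

        order = np.argsort(gidx, kind="mergesort")
        y, X, gidx = y[order], X[order], gidx[order]
        sizes = counts[gidx]

        first = np.r_[True, gidx[1:] != gidx[:-1]]
        singles = (sizes == 1) & first
        pair_a = (sizes == 2) & first
        pair_b = (sizes == 2) & ~first

        s2 = np.sqrt(2.0)
        Xs, ys = X[singles], y[singles]
        Xsum = (X[pair_a] + X[pair_b]) / s2
        ysum = (y[pair_a] + y[pair_b]) / s2
        Xdif = (X[pair_a] - X[pair_b]) / s2
        ydif = (y[pair_a] - y[pair_b]) / s2

        def xprod(A, b):
            return A.T @ A, A.T @ b, float(b @ b)

        self.A1, self.b1, self.c1 = xprod(Xs, ys)
        self.A2, self.b2, self.c2 = xprod(Xsum, ysum)
        self.Ac, self.bc, self.cc = xprod(Xdif, ydif)
        self.n1 = int(singles.sum())
        self.n2 = int(pair_a.sum())
        self.n = len(y)
        self.p = X.shape[1]
        self.n_groups = len(codes)

    def _assemble(self, lam: float):
        w1, w2 = 1.0 / (1.0 + lam), 1.0 / (1.0 + 2.0 * lam)
        A = self.Ac + w1 * self.A1 + w2 * self.A2
        b = self.bc + w1 * self.b1 + w2 * self.b2
        c = self.cc + w1 * self.c1 + w2 * self.c2
        return A, b, c

    def gls(self, lam: float):
        """Return (beta_hat, RSS, logdet(X' W X), A) at variance ratio lam."""
        A, b, c = self._assemble(lam)
        try:
            cf = linalg.cho_factor(A, check_finite=False)
            beta = linalg.cho_solve(cf, b, check_finite=False)
            logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        except linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(A, b, rcond=None)
            sign, logdet = np.linalg.slogdet(A)
            if sign <= 0:
                logdet = np.inf
        rss = max(c - b @ beta, 1e-300)
        return beta, rss, logdet, A

    def logdet_v(self, lam: float) -> float:
        return self.n1 * np.log1p(lam) + self.n2 * np.log1p(2.0 * lam)

    def profiled_neg2_reml(self, lam: float) -> float:
        _, rss, logdet_xwx, _ = self.gls(lam)
        dfree = self.n - self.p
        s2 = rss / dfree
        return (dfree * np.log(s2) + self.logdet_v(lam) + logdet_xwx
                + dfree * (1.0 + np.log(2.0 * np.pi)))

    def profiled_neg2_ml(self, lam: float) -> float:
        _, rss, _, _ = self.gls(lam)
        s2 = rss / self.n
        return (self.n * np.log(s2) + self.logdet_v(lam)
                + self.n * (1.0 + np.log(2.0 * np.pi)))

    def reml_loglik(self, sigma2_mu: float, sigma2_eps: float) -> float:
        """Restricted log-likelihood at the given variance components."""
        if sigma2_eps <= 0 or sigma2_mu < 0:
            return -np.inf
        lam = sigma2_mu / sigma2_eps
        _, rss, logdet_xwx, _ = self.gls(lam)
        dfree = self.n - self.p
        val = (dfree * np.log(sigma2_eps) + self.logdet_v(lam) + logdet_xwx
               + rss / sigma2_eps + dfree * np.log(2.0 * np.pi))
        return -0.5 * val

    def coef_variances(self, sigma2_mu: float, sigma2_eps: float) -> np.ndarray:
        """Diagonal of cov(beta_hat) at the given variance components."""
        lam = sigma2_mu / sigma2_eps
        A, _, _ = self._assemble(lam)
        Ainv = np.linalg.pinv(A)
        return sigma2_eps * np.diag(Ainv)


@dataclass
class LmmFitResult:
    """Fit of the random-intercept model for one outcome."""

    params: np.ndarray
    se: np.ndarray
    sigma2_mu: float
    sigma2_eps: float
    loglik: float
    converged: bool
    boundary: bool
    n_obs: int
    n_groups: int
    method: str
    param_names: list = field(default_factory=list)
    cov_params: np.ndarray | None = None
    aliased: list = field(default_factory=list)
    _problem: _RIProblem | None = field(default=None, repr=False)

    def tvalues(self) -> np.ndarray:
        return self.params / self.se


def _drop_aliased(X: np.ndarray, names: list) -> tuple[np.ndarray, list, list]:
    """Drop linearly dependent columns (pivoted QR)."""
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    dropped = [names[j] for j in sorted(piv[rank:])]
    return X[:, keep], [names[j] for j in keep], dropped


def fit_random_intercept_lmm(
    y, X, groups, method: str = "REML", param_names=None
) -> LmmFitResult:
    """Fit the random-intercept LMM by (restricted) maximum likelihood.

    Parameters
    ----------
    y, X, groups
        Outcome vector, fixed-effects design matrix and per-row group
        (individual) identifiers.  Rows with missing y or X are dropped.
    method
        ``REML`` (default) or ``ML``.
    param_names
        Optional column names for reporting.

    Returns
    -------
    LmmFitResult
        Estimates, standard errors from the GLS covariance at the optimum,
        variance components, restricted log-likelihood, and flags:
        ``boundary`` when sigma2_mu is estimated at zero, ``converged``
        False when the optimizer failed (the boundary fit is returned).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    names = list(param_names) if param_names is not None else [f"x{j}" for j in range(X.shape[1])]
    obs = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    y, X, groups = y[obs], X[obs], groups[obs]
    if y.size < X.shape[1] + 2:
        raise ValueError("not enough observations to fit the model")

    X, kept_names, dropped = _drop_aliased(X, names)
    if dropped:
        warnings.warn(f"dropping aliased fixed-effect columns: {dropped}")

    prob = _RIProblem(y, X, groups)
    objective = prob.profiled_neg2_reml if method == "REML" else prob.profiled_neg2_ml

    lo, hi = _LOG_LAMBDA_BOUNDS
    grid = np.linspace(lo, hi, 41)
    vals = np.array([objective(np.exp(g)) for g in grid])
    i = int(np.argmin(vals))
    converged = True
    bl = grid[max(i - 1, 0)]
    bh = grid[min(i + 1, grid.size - 1)]
    try:
        res = optimize.minimize_scalar(
            lambda t: objective(np.exp(t)), bounds=(bl, bh), method="bounded",
            options={"xatol": 1e-10},
        )
        best_t, best_val = float(res.x), float(res.fun)
        if not res.success:
            converged = False
    except Exception:
        converged = False
        best_t, best_val = grid[i], vals[i]

    # Explicit boundary check: lambda -> 0 is ordinary least squares.
    val0 = objective(0.0)
    if val0 <= best_val:
        lam_hat, best_val, boundary = 0.0, val0, True
    else:
        lam_hat = np.exp(best_t)
        boundary = lam_hat < _BOUNDARY_LAMBDA

    beta, rss, _, A = prob.gls(lam_hat)
    dfree = prob.n - prob.p if method == "REML" else prob.n
    sigma2_eps = rss / dfree
    sigma2_mu = lam_hat * sigma2_eps
    cov = sigma2_eps * np.linalg.pinv(A)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    loglik = prob.reml_loglik(sigma2_mu, sigma2_eps) if method == "REML" else -0.5 * best_val

    return LmmFitResult(
        params=beta, se=se, sigma2_mu=float(sigma2_mu), sigma2_eps=float(sigma2_eps),
        loglik=float(loglik), converged=converged, boundary=bool(boundary),
        n_obs=prob.n, n_groups=prob.n_groups, method=method,
        param_names=kept_names, cov_params=cov, aliased=dropped, _problem=prob,
    )


def satterthwaite_df(fit: LmmFitResult) -> np.ndarray:
    """Satterthwaite-approximated denominator df per fixed effect.

    df_k = 2 * Var(beta_k)^2 / (g' A g), with g the gradient of
    Var(beta_k) with respect to (sigma2_mu, sigma2_eps) and A the
    asymptotic covariance of the variance-component estimates (twice the
    inverse Hessian of the REML deviance), both obtained by central finite
    differences.  At the sigma2_mu = 0 boundary the OLS residual df is
    returned.
    """
    prob = fit._problem
    p = prob.p
    ols_df = float(prob.n - p)
    if fit.boundary or fit.sigma2_mu <= _BOUNDARY_LAMBDA * fit.sigma2_eps:
        return np.full(p, ols_df)

    theta = np.array([fit.sigma2_mu, fit.sigma2_eps])
    h = np.maximum(1e-4 * theta, 1e-10)

    def dev(t):
        return -2.0 * prob.reml_loglik(t[0], t[1])

    H = np.empty((2, 2))
    f0 = dev(theta)
    for a in range(2):
        ea = np.eye(2)[a] * h[a]
        H[a, a] = (dev(theta + ea) - 2.0 * f0 + dev(theta - ea)) / h[a] ** 2
    eab = np.array([h[0], h[1]])
    H[0, 1] = H[1, 0] = (
        dev(theta + eab) - dev(theta + np.array([h[0], -h[1]]))
        - dev(theta + np.array([-h[0], h[1]])) + dev(theta - eab)
    ) / (4.0 * h[0] * h[1])

    try:
        Acov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full(p, ols_df)
    if not np.all(np.isfinite(Acov)):
        return np.full(p, ols_df)

    var0 = prob.coef_variances(theta[0], theta[1])
    grads = np.empty((p, 2))
    for a in range(2):
        ea = np.eye(2)[a] * h[a]
        vp = prob.coef_variances(*(theta + ea))
        vm = prob.coef_variances(*(theta - ea))
        grads[:, a] = (vp - vm) / (2.0 * h[a])

    denom = np.einsum("ka,ab,kb->k", grads, Acov, grads)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * var0**2 / denom
    bad = ~np.isfinite(df) | (df <= 0)
    if bad.any():
        warnings.warn("non-positive Satterthwaite df; falling back to normal approximation")
        df[bad] = np.inf
    return df


def lmm_pvalues(fit: LmmFitResult, df_method: str = "satterthwaite") -> np.ndarray:
    """Two-sided p-values for the fixed effects of a fitted model.

    ``satterthwaite`` uses a t reference with Satterthwaite-approximated
    df (the lme4/lmerTest convention); ``normal`` uses the z approximation.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.params / fit.se
    if df_method == "normal":
        return 2.0 * stats.norm.sf(np.abs(t))
    if df_method != "satterthwaite":
        raise ValueError("df_method must be 'satterthwaite' or 'normal'")
    df = satterthwaite_df(fit)
    pvals = np.where(np.isinf(df), 2.0 * stats.norm.sf(np.abs(t)),
                     2.0 * stats.t.sf(np.abs(t), np.where(np.isinf(df), 1.0, df)))
    return pvals
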