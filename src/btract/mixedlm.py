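"""Random-intercept linear mixed model, fit by profiled REML.

The model is

    y_i = x_i' beta + u_{g(i)} + eps_i,   u_j ~ N(0, tau2),  eps_i ~ N(0, sigma2)

for grouping (subject) index g.  Writing theta = tau2 / sigma2, the marginal
covariance is sigma2 * (I + theta * Z Z') with Z the group indicator matrix.
Both beta and sigma2 have closed forms given theta, so (RE)ML reduces to a
one-dimensional optimization over theta.  Per-group inverses come from the
Sherman-Morrison identity, so each objective evaluation costs O(G p^2) after
an O(N p^2) precomputation; this is what makes the massed pairwise edge fits
and the permutation null affordable.

Fixed-effect inference is the Wald z test on beta / se(beta), the same
convention as statsmodels' MixedLM summaries, which serves as the
independent numerical cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["MixedFit", "fit_random_intercept"]

# Bounds for log(theta); theta below exp(-12) is numerically an OLS fit.
_LOG_THETA_BOUNDS = (-12.0, 10.0)


@dataclass
class MixedFit:
    """Result of a random-intercept fit."""

    beta: np.ndarray          # fixed-effect estimates, one per column of X
    se: np.ndarray            # Wald standard errors
    p: np.ndarray             # two-sided normal p-values
    sigma2: float             # residual variance
    tau2: float               # random-intercept variance
    n_obs: int
    n_groups: int
    ols_fallback: bool        # True when the intercept variance hit zero

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se


def _group_codes(groups: np.ndarray) -> tuple[np.ndarray, int]:
    _, codes = np.unique(groups, return_inverse=True)
    return codes, int(codes.max()) + 1 if codes.size else 0


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    reml: bool = True,
) -> MixedFit:
    """Fit ``y = X beta + u_group + eps`` with a per-group random intercept.

    Parameters
    ----------
    y : (n,) response vector.
    X : (n, p) fixed-effect design (include the intercept column).
    groups : (n,) group labels (any hashable dtype).
    reml : use restricted maximum likelihood (default) or ML.

    Notes
    -----
    With a single group the variance ratio is unidentified and the fit
    degenerates to ordinary least squares (``ols_fallback`` is set), as does
    any fit whose REML-optimal intercept variance is zero.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    N, p = X.shape
    if y.shape[0] != N:
        raise ValueError("y and X have incompatible lengths")
    codes, G = _group_codes(np.asarray(groups))
    if N <= p:
        raise ValueError(f"need more than {p} observations, got {N}")

    # Sufficient statistics.
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    n_j = np.bincount(codes, minlength=G).astype(float)
    Sy = np.bincount(codes, weights=y, minlength=G)
    Sx = np.zeros((G, p))
    for k in range(p):
        Sx[:, k] = np.bincount(codes, weights=X[:, k], minlength=G)

    df = N - p if reml else N

    def _solve(theta: float):
        c = theta / (1.0 + theta * n_j)          # per-group shrinkage
        A = XtX - (Sx * c[:, None]).T @ Sx       # X' V*^-1 X
        b = Xty - Sx.T @ (c * Sy)                # X' V*^-1 y
        beta = np.linalg.solve(A, b)
        Sr = Sy - Sx @ beta                      # per-group residual sums
        rVr = (
            yty - 2.0 * beta @ Xty + beta @ XtX @ beta - float(c @ (Sr**2))
        )
        return A, beta, max(rVr, 1e-300)

    def negloglik(log_theta: float) -> float:
        theta = float(np.exp(log_theta))
        try:
            A, _, rVr = _solve(theta)
        except np.linalg.LinAlgError:
            return np.inf
        sigma2 = rVr / df
        ll = df * np.log(sigma2) + float(np.sum(np.log1p(theta * n_j)))
        if reml:
            sign, logdet = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            ll += logdet
        return 0.5 * ll

    if G <= 1:
        theta_hat, fallback = 0.0, True
    else:
        res = optimize.minimize_scalar(
            negloglik, bounds=_LOG_THETA_BOUNDS, method="bounded",
            options={"xatol": 1e-6},
        )
        theta_hat = float(np.exp(res.x))
        fallback = res.x <= _LOG_THETA_BOUNDS[0] + 1e-3
        if fallback or negloglik(_LOG_THETA_BOUNDS[0]) < res.fun:
            theta_hat, fallback = 0.0, True

    A, beta, rVr = _solve(theta_hat)
    sigma2 = rVr / df
    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return MixedFit(
        beta=beta,
        se=se,
        p=pvals,
        sigma2=float(sigma2),
        tau2=float(theta_hat * sigma2),
        n_obs=N,
        n_groups=G,
        ols_fallback=bool(fallback),
    )
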