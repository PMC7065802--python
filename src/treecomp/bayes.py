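"""Exact conjugate Bayesian linear regression with a Normal-Inverse-Gamma prior.

The growth model is an ordinary Gaussian linear regression
``y = X beta + eps``, ``eps ~ Normal(0, sigma^2 I)``.  Placing the conjugate
joint prior ``(beta, sigma^2) ~ NIG(mu0, V0, a0, b0)`` yields a closed-form
NIG posterior, multivariate-t marginals for ``beta``, an Inverse-Gamma
marginal for ``sigma^2``, and a multivariate-t posterior predictive.  The
closed form is the point: it makes the thousands of refits required by
permutation testing and spatial cross-validation cheap.

All solves go through a symmetric positive-definite Cholesky factorisation of
the posterior precision ``V0^-1 + X'X``; no explicit matrix inverse is formed
except to report ``V*`` itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import linalg, sparse, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "NIGParams",
    "MvtParams",
    "FitResult",
    "nig_update",
    "marginal_beta",
    "marginal_sigma",
    "posterior_predictive",
    "predictive_marginals",
    "rmse",
    "residuals",
    "BayesianLinearRegression",
]


def _as_spd_matrix(V: Union[float, Sequence[float], np.ndarray], p: int) -> np.ndarray:
    """Expand scalar/diagonal shorthand for the prior shape matrix to p x p."""
    V = np.asarray(V, dtype=float)
    if V.ndim == 0:
        return float(V) * np.eye(p)
    if V.ndim == 1:
        if V.shape[0] != p:
            raise ValueError(f"diagonal prior shape has length {V.shape[0]}, expected {p}")
        return np.diag(V)
    if V.shape != (p, p):
        raise ValueError(f"prior shape matrix is {V.shape}, expected ({p}, {p})")
    return V


@dataclass
class NIGParams:
    """Normal-Inverse-Gamma hyperparameters (mu, V, a, b).

    Used for both the prior and the posterior: ``beta | sigma^2 ~
    Normal(mu, sigma^2 V)`` and ``sigma^2 ~ InverseGamma(a, b)``.
    """

    mu: np.ndarray
    V: np.ndarray
    a: float
    b: float

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.V = _as_spd_matrix(self.V, self.mu.shape[0])
        if not np.allclose(self.V, self.V.T):
            raise ValueError("V must be symmetric")
        try:
            linalg.cholesky(self.V, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError("V must be positive definite") from exc
        if not (self.a > 0 and self.b > 0):
            raise ValueError("a and b must be positive")

    @property
    def p(self) -> int:
        return self.mu.shape[0]


@dataclass
class MvtParams:
    """Multivariate Student-t parameters: location, shape matrix, dof.

    The shape matrix is not the covariance; ``cov = shape * dof / (dof - 2)``
    for ``dof > 2``.
    """

    loc: np.ndarray
    shape: np.ndarray
    dof: float

    def __post_init__(self) -> None:
        self.loc = np.atleast_1d(np.asarray(self.loc, dtype=float))
        self.shape = np.atleast_2d(np.asarray(self.shape, dtype=float))
        if self.dof <= 0:
            raise ValueError("dof must be positive")

    @property
    def mean(self) -> np.ndarray:
        return self.loc

    def cov(self) -> np.ndarray:
        if self.dof <= 2:
            raise ValueError("covariance undefined for dof <= 2")
        return self.shape * self.dof / (self.dof - 2.0)

    def marginal_scale(self) -> np.ndarray:
        """Per-coordinate t scale (sqrt of the shape diagonal)."""
        return np.sqrt(np.diag(self.shape))

    def marginal_interval(self, level: float = 0.95) -> np.ndarray:
        """Equal-tailed per-coordinate credible intervals, shape (p, 2)."""
        q = stats.t.ppf(0.5 + level / 2.0, df=self.dof)
        s = self.marginal_scale()
        return np.column_stack([self.loc - q * s, self.loc + q * s])

    def logpdf(self, x: np.ndarray) -> float:
        return float(
            stats.multivariate_t(loc=self.loc, shape=self.shape, df=self.dof).logpdf(x)
        )


def _gram(X) -> tuple[np.ndarray, int]:
    """Return (X'X as dense, n) for a dense or scipy.sparse design."""
    if sparse.issparse(X):
        return np.asarray((X.T @ X).todense()), X.shape[0]
    X = np.asarray(X, dtype=float)
    return X.T @ X, X.shape[0]


def nig_update(prior: NIGParams, X, y: np.ndarray) -> NIGParams:
    """Conjugate NIG posterior update for Gaussian regression data (X, y).

    mu* = (V0^-1 + X'X)^-1 (V0^-1 mu0 + X'y)
    V*  = (V0^-1 + X'X)^-1
    a*  = a0 + n/2
    b*  = b0 + (mu0' V0^-1 mu0 + y'y - mu*' V*^-1 mu*) / 2

    With no data the posterior is the prior exactly.
    """
    y = np.asarray(y, dtype=float).ravel()
    if X is None or (hasattr(X, "shape") and X.shape[0] == 0):
        if y.size != 0:
            raise ValueError("empty design with non-empty response")
        return NIGParams(prior.mu.copy(), prior.V.copy(), prior.a, prior.b)

    XtX, n = _gram(X)
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]}")
    p = prior.p
    if XtX.shape[0] != p:
        raise ValueError(f"X has {XtX.shape[0]} columns but prior has dimension {p}")

    Xty = np.asarray(X.T @ y, dtype=float).ravel()
    V0_chol = linalg.cho_factor(prior.V, lower=True)
    V0_inv = linalg.cho_solve(V0_chol, np.eye(p))
    precision = V0_inv + XtX
    precision = 0.5 * (precision + precision.T)
    try:
        prec_chol = linalg.cho_factor(precision, lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "posterior precision V0^-1 + X'X is numerically singular; "
            "use a proper (finite-variance) prior"
        ) from exc

    rhs = V0_inv @ prior.mu + Xty
    mu_star = linalg.cho_solve(prec_chol, rhs)
    V_star = linalg.cho_solve(prec_chol, np.eye(p))
    V_star = 0.5 * (V_star + V_star.T)
    a_star = prior.a + n / 2.0
    # mu*' V*^-1 mu* = mu*' (precision) mu*
    quad = float(prior.mu @ (V0_inv @ prior.mu) + y @ y - mu_star @ (precision @ mu_star))
    b_star = prior.b + 0.5 * quad
    if b_star <= 0:
        # guard against catastrophic cancellation on near-perfect fits
        b_star = max(b_star, np.finfo(float).tiny)
    return NIGParams(mu_star, V_star, a_star, b_star)


def marginal_beta(nig: NIGParams) -> MvtParams:
    """Marginal law of the coefficients: Mv-t(mu, (b/a) V, 2a)."""
    return MvtParams(nig.mu.copy(), (nig.b / nig.a) * nig.V, 2.0 * nig.a)


def marginal_sigma(nig: NIGParams) -> tuple[float, float]:
    """Marginal law of sigma^2: InverseGamma(a, b), returned as (a, b)."""
    return (nig.a, nig.b)


def posterior_predictive(nig: NIGParams, Xnew) -> MvtParams:
    """Predictive law of new responses at design Xnew.

    Multivariate-t with location X~ mu, shape (b/a)(I + X~ V X~'), dof 2a.
    Forms the full m x m shape matrix; for per-row marginals at scale use
    :func:`predictive_marginals`.
    """
    if sparse.issparse(Xnew):
        Xnew = np.asarray(Xnew.todense())
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != nig.p:
        raise ValueError(f"Xnew has {Xnew.shape[1]} columns, expected {nig.p}")
    loc = Xnew @ nig.mu
    shape = (nig.b / nig.a) * (np.eye(Xnew.shape[0]) + Xnew @ nig.V @ Xnew.T)
    return MvtParams(loc, shape, 2.0 * nig.a)


def predictive_marginals(nig: NIGParams, Xnew) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-row predictive marginals (loc, t-scale, dof) without the m x m matrix."""
    if sparse.issparse(Xnew):
        XV = np.asarray((Xnew @ nig.V))
        quad = np.asarray(Xnew.multiply(XV).sum(axis=1)).ravel()
        loc = np.asarray(Xnew @ nig.mu).ravel()
    else:
        Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
        XV = Xnew @ nig.V
        quad = np.einsum("ij,ij->i", Xnew, XV)
        loc = Xnew @ nig.mu
    scale = np.sqrt((nig.b / nig.a) * (1.0 + quad))
    return loc, scale, 2.0 * nig.a


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error sqrt(sum (y - yhat)^2 / n) over all trees."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} vs {yhat.shape[0]}")
    if y.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass
class FitResult:
    """A fitted growth model: posterior, fitted values, in-sample RMSE."""

    posterior: NIGParams
    fitted: np.ndarray
    rmse_insample: float
    columns: list = field(default_factory=list)

    def coef_table(self):
        """Coefficient table: name, posterior mean, marginal-t scale, dof.

        Enough to reconstruct every marginal credible interval, plus a final
        row for the error variance (Inverse-Gamma a, b encoded as scale/dof
        columns holding a and b).
        """
        import pandas as pd

        beta = marginal_beta(self.posterior)
        names = list(self.columns) if self.columns else [
            f"coef_{i}" for i in range(self.posterior.p)
        ]
        tab = pd.DataFrame(
            {
                "parameter": names,
                "mean": beta.loc,
                "scale": beta.marginal_scale(),
                "dof": beta.dof,
            }
        )
        a, b = marginal_sigma(self.posterior)
        sig = pd.DataFrame(
            {
                "parameter": ["sigma2"],
                "mean": [b / (a - 1.0) if a > 1 else np.nan],
                "scale": [b],
                "dof": [a],
            }
        )
        return pd.concat([tab, sig], ignore_index=True)


def residuals(fit: FitResult, dataset) -> "object":
    """Per-tree residual table (tag, x, y, residual) for spatial mapping."""
    import pandas as pd

    frame = dataset.frame
    resid = np.asarray(frame["y"], dtype=float) - np.asarray(fit.fitted, dtype=float)
    return pd.DataFrame(
        {
            "tag": frame["focal_tag"].to_numpy(),
            "x": frame["x"].to_numpy(),
            "y_coord": frame["y_coord"].to_numpy(),
            "residual": resid,
        }
    )


class BayesianLinearRegression(BaseEstimator, RegressorMixin):
    """Gaussian linear regression with an exact conjugate NIG posterior.

    Parameters
    ----------
    mu0 : float or array, default 0.0
        Prior coefficient mean (scalar is broadcast).
    V0 : float, array or matrix, default 100.0
        Prior shape matrix for the coefficients; scalar c means c*I, a
        vector means a diagonal.
    a0, b0 : float, default 0.01
        Inverse-Gamma shape and scale for the error variance.

    Attributes
    ----------
    posterior_ : NIGParams
        The exact joint posterior after :meth:`fit`.
    coef_ : ndarray
        Posterior mean of the coefficients (the predictive point estimate).
    """

    def __init__(self, mu0=0.0, V0=100.0, a0=0.01, b0=0.01):
        self.mu0 = mu0
        self.V0 = V0
        self.a0 = a0
        self.b0 = b0

    def _prior(self, p: int) -> NIGParams:
        mu0 = np.asarray(self.mu0, dtype=float)
        if mu0.ndim == 0:
            mu0 = np.full(p, float(mu0))
        return NIGParams(mu0, _as_spd_matrix(self.V0, p), float(self.a0), float(self.b0))

    def fit(self, X, y):
        if not sparse.issparse(X):
            X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        self.n_features_in_ = X.shape[1]
        self.prior_ = self._prior(X.shape[1])
        self.posterior_ = nig_update(self.prior_, X, y)
        self.coef_ = self.posterior_.mu
        return self

    def predict(self, X):
        """Posterior-predictive means X mu* (the model's fitted values)."""
        check_is_fitted(self, "posterior_")
        loc, _, _ = predictive_marginals(self.posterior_, X)
        return loc

    def predict_dist(self, X) -> MvtParams:
        """Full joint posterior predictive distribution at X."""
        check_is_fitted(self, "posterior_")
        return posterior_predictive(self.posterior_, X)

    def coef_interval(self, level: float = 0.95) -> np.ndarray:
        check_is_fitted(self, "posterior_")
        return marginal_beta(self.posterior_).marginal_interval(level)
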