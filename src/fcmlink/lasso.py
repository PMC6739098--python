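"""The weighted Lasso estimator used by stability selection and evaluation.

Minimizes ``||y - X beta||^2 + lam * sum_j w_j |beta_j|`` by cyclic
coordinate descent (see :mod:`fcmlink._solver` for the kernel and the
threshold algebra).  Note there is no 1/(2n) factor in front of the residual
sum of squares: penalties here are on the scale of the printed objective, so
``beta = 0`` exactly once ``lam >= 2 * max_j |x_j' y|`` (KKT bound, centered
data, unit weights).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._solver import cd_gram

__all__ = ["LassoFit", "lasso_fit"]


@dataclass
class LassoFit:
    beta: np.ndarray
    intercept: float
    lam: float
    n_iter: int
    converged: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta + self.intercept

    def objective(self, X: np.ndarray, y: np.ndarray, weights=None) -> float:
        w = np.ones_like(self.beta) if weights is None else np.asarray(weights, float)
        resid = y - self.predict(X)
        return float(resid @ resid + self.lam * np.sum(w * np.abs(self.beta)))


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    weights: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    fit_intercept: bool = True,
) -> LassoFit:
    """Fit the weighted Lasso at a single penalty.

    ``weights`` are per-variable penalty multipliers (all positive); the
    randomized Lasso passes w_j in {alpha, 1}.  The intercept is obtained by
    centering X and y before the fit.  A fit that does not reach the
    stationarity tolerance within ``max_iter`` sweeps is returned with
    ``converged=False`` and a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    p = X.shape[1]
    w = np.ones(p) if weights is None else np.asarray(weights, dtype=float).ravel()
    if w.shape != (p,) or np.any(w <= 0):
        raise ValueError("weights must be positive, one per column")

    if fit_intercept:
        xm = X.mean(axis=0)
        ym = y.mean()
        Xc = X - xm
        yc = y - ym
    else:
        xm = np.zeros(p)
        ym = 0.0
        Xc, yc = X, y

    G = Xc.T @ Xc
    c = Xc.T @ yc
    beta, n_iter, converged = cd_gram(G, c, lam, w, tol=tol, max_iter=max_iter)
    if not converged:
        warnings.warn(f"lasso_fit did not converge in {max_iter} sweeps", RuntimeWarning)
    intercept = float(ym - xm @ beta) if fit_intercept else 0.0
    return LassoFit(beta=beta, intercept=intercept, lam=float(lam), n_iter=n_iter, converged=converged)
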