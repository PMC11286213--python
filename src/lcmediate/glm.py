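"""Weighted logistic maximum likelihood with Firth fallback.

Newton–Raphson fitting of a Bernoulli logistic model with (possibly
negative) frequency weights.  Negative weights arise in the BCH
bias-adjusted three-step estimator, where individuals are expanded into
weighted pseudo-rows using the inverse classification-error matrix, so a
standard GLM routine (which rejects negative weights) cannot be used.

Separation (perfect prediction) is detected and, on request, resolved by
refitting with the Firth/Jeffreys penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = ["LogisticFit", "fit_logistic", "SeparationWarning"]

_COEF_DIVERGED = 12.0
_PROB_EPS = 1e-8


class SeparationWarning(UserWarning):
    """Raised as a warning when a logistic fit shows perfect prediction."""


@dataclass
class LogisticFit:
    """Result of a weighted logistic maximum-likelihood fit."""

    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    separation: bool
    method: str = "ML"
    n_iter: int = 0
    se: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.se = np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, dtype=float) @ self.coef)


def _loglik(y, p, w):
    # Bernoulli log-likelihood; clip keeps boundary fits finite.
    p = np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)
    return float(np.sum(w * (y * np.log(p) + (1.0 - y) * np.log1p(-p))))


def _newton(X, y, w, firth: bool, max_iter: int, tol: float, start=None):
    n, q = X.shape
    wsum = np.sum(np.abs(w))
    if start is not None:
        beta = np.asarray(start, dtype=float).copy()
    else:
        beta = np.zeros(q)
        ybar = float(np.clip(np.sum(np.abs(w) * y) / wsum, 0.01, 0.99))
        beta[0] = np.log(ybar / (1.0 - ybar))

    def penalized_ll(b):
        p = expit(X @ b)
        ll = _loglik(y, p, w)
        if firth:
            W = w * p * (1.0 - p)
            sign, logdet = np.linalg.slogdet(X.T @ (W[:, None] * X))
            ll += 0.5 * logdet if sign > 0 else -np.inf
        return ll

    ll = penalized_ll(beta)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        p = expit(X @ beta)
        W = w * p * (1.0 - p)
        info = X.T @ (W[:, None] * X)
        resid = w * (y - p)
        if firth:
            # Jeffreys-prior score correction via hat-matrix leverages.
            try:
                info_inv = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                info_inv = np.linalg.pinv(info)
            h = np.einsum("ij,jk,ik->i", X, info_inv, X) * W
            resid = resid + h * (0.5 - p)
        score = X.T @ resid
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving line search on the (penalized) log-likelihood
        new_ll = -np.inf
        for _ in range(25):
            cand = beta + step
            new_ll = penalized_ll(cand)
            if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                break
            step = step / 2.0
        beta, old_ll, ll = cand, ll, new_ll
        if abs(ll - old_ll) < tol * (abs(old_ll) + 1.0) and np.max(np.abs(score)) < 1e-4 * (1 + wsum):
            converged = True
            break
    p = expit(X @ beta)
    info = X.T @ ((w * p * (1.0 - p))[:, None] * X)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return beta, cov, _loglik(y, p, w), converged, n_iter


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    firth: bool = False,
    firth_on_separation: bool = True,
    max_iter: int = 100,
    tol: float = 1e-12,
    start: np.ndarray | None = None,
) -> LogisticFit:
    """Fit a logistic regression by weighted ML.

    Parameters
    ----------
    X : (n, q) design matrix including the intercept column.
    y : (n,) binary response.
    weights : optional (n,) frequency weights; negative values allowed
        (BCH pseudo-rows).  ``None`` means all ones.
    firth : fit with the Firth/Jeffreys penalty from the start.
    firth_on_separation : if a plain ML fit shows perfect prediction,
        silently refit with the Firth penalty (the recommended remedy for
        separation in sparse exposure-by-mediator cells).

    Returns
    -------
    LogisticFit
        Coefficients, observed-information covariance (inverse Fisher
        information at the estimate; for frequency weights all equal to
        ``c`` this scales the covariance by ``1/c``), and diagnostics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0] or len(w) != X.shape[0]:
        raise ValueError("X, y and weights have inconsistent shapes")
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")

    beta, cov, ll, converged, n_iter = _newton(X, y, w, firth, max_iter, tol, start)
    p = expit(X @ beta)
    active = w != 0
    boundary = np.any((p[active] < _PROB_EPS) | (p[active] > 1 - _PROB_EPS))
    separation = bool(boundary and np.max(np.abs(beta)) > _COEF_DIVERGED)
    method = "Firth" if firth else "ML"
    if separation and not firth and firth_on_separation:
        fit = fit_logistic(X, y, weights, firth=True, max_iter=max_iter, tol=tol, start=start)
        fit.separation = True
        return fit
    if separation and not firth:
        warnings.warn("perfect prediction detected in logistic fit", SeparationWarning)
    return LogisticFit(beta, cov, ll, converged, separation, method, n_iter)
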