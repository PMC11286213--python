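"""Structural mediation models and counterfactual effects.

Two logistic models define the structural part of the analysis for a
categorical exposure W (k classes, reference class last), binary mediator
M and binary outcome Y, with an exposure-mediator interaction:

    P(Y=1 | W, M, C) = expit(b0 + b1*M + sum_d b_{2+d} X_d
                             + sum_d b_{...} X_d*M + C*g)
    P(M=1 | W, C)    = expit(a0 + sum_d a_{1+d} X_d + C*h)

where X_d = 1(W = d) for the k-1 non-reference classes.  Counterfactual
effects are obtained by direct application of the mediation formula

    E[Y(x, M(x*))] = sum_m P(Y=1 | x, m) P(M=m | x*)

(averaged over the empirical confounder distribution when confounders are
present, i.e. marginal standardization), and reported per non-reference
class x as log risk ratios:

    TE   = ln E[Y(x,M(x))]   - ln E[Y(ref,M(ref))]
    TNIE = ln E[Y(x,M(x))]   - ln E[Y(x,M(ref))]
    PNDE = ln E[Y(x,M(ref))] - ln E[Y(ref,M(ref))]

so that TE = TNIE + PNDE holds identically.  Standard errors come from
the delta method with central finite-difference gradients over the
stacked (alpha, beta) parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .glm import LogisticFit, fit_logistic

__all__ = [
    "StructuralParams",
    "MediationEffects",
    "outcome_design",
    "mediator_design",
    "fit_outcome_model",
    "fit_mediator_model",
    "fit_structural",
    "potential_outcome",
    "mediation_effects",
]

ESTIMANDS = ("te", "tnie", "pnde")


def _class_dummies(W: np.ndarray, k: int) -> np.ndarray:
    """n x (k-1) dummies for classes 0..k-2; class k-1 is the reference."""
    W = np.asarray(W)
    return (W[:, None] == np.arange(k - 1)[None, :]).astype(float)


def mediator_design(W: np.ndarray, k: int, C: np.ndarray | None = None) -> np.ndarray:
    """Design [1, X_1..X_{k-1}, C] for the mediator model."""
    cols = [np.ones((len(W), 1)), _class_dummies(W, k)]
    if C is not None:
        cols.append(np.atleast_2d(np.asarray(C, dtype=float)).reshape(len(W), -1))
    return np.hstack(cols)


def outcome_design(
    W: np.ndarray, M: np.ndarray, k: int, C: np.ndarray | None = None
) -> np.ndarray:
    """Design [1, M, X_1..X_{k-1}, X_1*M..X_{k-1}*M, C] for the outcome model."""
    X = _class_dummies(W, k)
    M = np.asarray(M, dtype=float)
    cols = [np.ones((len(W), 1)), M[:, None], X, X * M[:, None]]
    if C is not None:
        cols.append(np.atleast_2d(np.asarray(C, dtype=float)).reshape(len(W), -1))
    return np.hstack(cols)


@dataclass
class StructuralParams:
    """Fitted coefficients of the mediator and outcome logistic models.

    ``alpha`` has length ``k + n_conf``; ``beta`` has length
    ``2k + n_conf``.  Covariances are the observed-information inverses
    from the respective fits.
    """

    alpha: np.ndarray
    beta: np.ndarray
    cov_alpha: np.ndarray
    cov_beta: np.ndarray
    k: int
    n_conf: int = 0
    fit_method: str = "ML"

    @property
    def n_alpha(self) -> int:
        return self.k + self.n_conf

    def theta(self) -> np.ndarray:
        return np.concatenate([self.alpha, self.beta])

    def cov_theta(self) -> np.ndarray:
        # block-diagonal: the two models are fit separately
        na, nb = len(self.alpha), len(self.beta)
        cov = np.zeros((na + nb, na + nb))
        cov[:na, :na] = self.cov_alpha
        cov[na:, na:] = self.cov_beta
        return cov

    @classmethod
    def from_theta(
        cls, theta: np.ndarray, k: int, n_conf: int = 0, **kw
    ) -> "StructuralParams":
        na = k + n_conf
        a, b = theta[:na], theta[na:]
        return cls(a, b, np.zeros((na, na)), np.zeros((len(b), len(b))), k, n_conf, **kw)


def aggregate_cells(W, M, Y, k: int):
    """Collapse (W, M, Y) rows to the 4k cross-tab cells with counts.

    The logistic fits depend on the data only through these cell counts,
    so confounder-free fits can run on 4k weighted rows regardless of n.
    """
    idx = np.asarray(W) * 4 + np.asarray(M) * 2 + np.asarray(Y)
    wts = np.bincount(idx, minlength=4 * k).astype(float)
    Wc = np.repeat(np.arange(k), 4)
    Mc = np.tile([0, 0, 1, 1], k).astype(float)
    Yc = np.tile([0, 1, 0, 1], k).astype(float)
    return Wc, Mc, Yc, wts


def fit_structural_fast(W, M, Y, k: int, firth_on_separation: bool = True) -> StructuralParams:
    """`fit_structural` on cell counts (no confounders, unit weights)."""
    Wc, Mc, Yc, wts = aggregate_cells(W, M, Y, k)
    return fit_structural(Wc, Mc, Yc, k, None, wts, firth_on_separation)


def fit_mediator_model(
    W, M, k: int, C=None, weights=None, firth_on_separation: bool = True
) -> LogisticFit:
    """ML logistic fit of M on class dummies (and confounder main effects)."""
    return fit_logistic(
        mediator_design(W, k, C), M, weights, firth_on_separation=firth_on_separation
    )


def fit_outcome_model(
    W, M, Y, k: int, C=None, weights=None, firth_on_separation: bool = True
) -> LogisticFit:
    """ML logistic fit of Y on M, class dummies and class-by-M interactions."""
    return fit_logistic(
        outcome_design(W, M, k, C), Y, weights, firth_on_separation=firth_on_separation
    )


def fit_structural(
    W, M, Y, k: int, C=None, weights=None, firth_on_separation: bool = True
) -> StructuralParams:
    """Fit both structural models and bundle the results."""
    fm = fit_mediator_model(W, M, k, C, weights, firth_on_separation)
    fy = fit_outcome_model(W, M, Y, k, C, weights, firth_on_separation)
    n_conf = 0 if C is None else np.atleast_2d(np.asarray(C)).reshape(len(np.asarray(M)), -1).shape[1]
    method = "Firth" if (fm.method == "Firth" or fy.method == "Firth") else "ML"
    return StructuralParams(fm.coef, fy.coef, fm.cov, fy.cov, k, n_conf, method)


# ---------------------------------------------------------------------------
# mediation formula
# ---------------------------------------------------------------------------


def _cond_probs(theta: np.ndarray, k: int, n_conf: int, C_rows: np.ndarray | None):
    """Return (p_m, p_y) with p_m[x] = P(M=1|x), p_y[x,m] = P(Y=1|x,m).

    With confounders the arrays gain a leading row axis and the caller
    averages the mediation formula over rows (marginal standardization).
    """
    na = k + n_conf
    alpha, beta = theta[:na], theta[na:]
    classes = np.arange(k)
    if n_conf and C_rows is None:
        raise ValueError("confounder rows required for a model fit with confounders")
    if n_conf:
        C_rows = np.atleast_2d(np.asarray(C_rows, dtype=float))
        r = len(C_rows)
        Wx = np.repeat(classes, r)
        Cx = np.tile(C_rows, (k, 1))
        p_m = expit(mediator_design(Wx, k, Cx) @ alpha).reshape(k, r).T
        p_y = np.empty((r, k, 2))
        for m in (0, 1):
            Mx = np.full(k * r, float(m))
            p_y[:, :, m] = expit(outcome_design(Wx, Mx, k, Cx) @ beta).reshape(k, r).T
    else:
        p_m = expit(mediator_design(classes, k) @ alpha)[None, :]
        p_y = np.empty((1, k, 2))
        for m in (0, 1):
            p_y[0, :, m] = expit(outcome_design(classes, np.full(k, float(m)), k) @ beta)
    return p_m, p_y


def _po_matrix(theta, k, n_conf, C_rows) -> np.ndarray:
    """PO[x, x*] = E[Y(x, M(x*))], standardized over confounder rows."""
    p_m, p_y = _cond_probs(theta, k, n_conf, C_rows)
    # per row: PO = p_y[:,x,0]*(1-p_m[:,x*]) + p_y[:,x,1]*p_m[:,x*]
    po = (
        p_y[:, :, 0][:, :, None] * (1.0 - p_m[:, None, :])
        + p_y[:, :, 1][:, :, None] * p_m[:, None, :]
    )
    return po.mean(axis=0)


def potential_outcome(
    sp: StructuralParams, x: int, x_star: int, C_rows: np.ndarray | None = None
) -> float:
    """E[Y(x, M(x*))] by the mediation formula under the fitted models."""
    if not (0 <= x < sp.k and 0 <= x_star < sp.k):
        raise ValueError("class labels out of range")
    po = _po_matrix(sp.theta(), sp.k, sp.n_conf, C_rows)[x, x_star]
    if po <= 0.0 or po >= 1.0:
        raise ValueError("degenerate potential-outcome probability")
    return float(po)


def _effects_vector(theta, k, n_conf, C_rows) -> np.ndarray:
    """Flattened (k-1, 3) array of [TE, TNIE, PNDE] log-RRs per class vs ref."""
    po = _po_matrix(theta, k, n_conf, C_rows)
    ref = k - 1
    out = np.empty((k - 1, 3))
    base = np.log(po[ref, ref])
    for x in range(k - 1):
        own = np.log(po[x, x])
        cross = np.log(po[x, ref])  # E[Y(x, M(ref))]
        out[x, 0] = own - base
        out[x, 1] = own - cross
        out[x, 2] = cross - base
    return out.ravel()


@dataclass
class MediationEffects:
    """TE / TNIE / PNDE per non-reference class, on the log risk-ratio scale.

    ``estimates`` and ``ses`` are (k-1, 3) arrays with columns ordered
    (TE, TNIE, PNDE) and rows ordered as the non-reference classes.
    """

    estimates: np.ndarray
    ses: np.ndarray
    class_names: list[str]
    scale: str = "log_rr"
    method: str = ""
    diagnostics: dict = field(default_factory=dict)

    @property
    def comparisons(self) -> list[str]:
        ref = self.class_names[-1]
        return [f"{c} vs {ref}" for c in self.class_names[:-1]]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per comparison x estimand, with RR and 95% CI."""
        rows = []
        for i, comp in enumerate(self.comparisons):
            for j, est in enumerate(ESTIMANDS):
                b, se = self.estimates[i, j], self.ses[i, j]
                rows.append(
                    {
                        "method": self.method,
                        "comparison": comp,
                        "estimand": est,
                        "estimate_logrr": b,
                        "se": se,
                        "rr": np.exp(b),
                        "ci_low": b - 1.96 * se,
                        "ci_high": b + 1.96 * se,
                    }
                )
        return pd.DataFrame(rows)

    def __getitem__(self, key: tuple[int, str]) -> tuple[float, float]:
        i, est = key
        j = ESTIMANDS.index(est)
        return float(self.estimates[i, j]), float(self.ses[i, j])


def mediation_effects(
    sp: StructuralParams,
    C_rows: np.ndarray | None = None,
    class_names: list[str] | None = None,
    se: bool = True,
    fd_step: float = 1e-5,
) -> MediationEffects:
    """Counterfactual mediation effects with delta-method standard errors.

    The gradient of each log-RR effect with respect to the stacked
    (alpha, beta) vector is computed by central finite differences with
    step ``fd_step`` and sandwiched with the block-diagonal coefficient
    covariance.
    """
    k = sp.k
    names = class_names or [f"class{i + 1}" for i in range(k)]
    theta = sp.theta()
    est = _effects_vector(theta, k, sp.n_conf, C_rows)
    if se:
        q = len(theta)
        grad = np.empty((len(est), q))
        for j in range(q):
            h = fd_step * max(1.0, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            grad[:, j] = (
                _effects_vector(tp, k, sp.n_conf, C_rows)
                - _effects_vector(tm, k, sp.n_conf, C_rows)
            ) / (2.0 * h)
        var = np.einsum("iq,qr,ir->i", grad, sp.cov_theta(), grad)
        ses = np.sqrt(np.clip(var, 0.0, None))
    else:
        ses = np.zeros_like(est)
    return MediationEffects(
        est.reshape(k - 1, 3), ses.reshape(k - 1, 3), list(names), method=""
    )
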