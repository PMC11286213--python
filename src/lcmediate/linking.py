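"""Estimators connecting a latent class exposure to the mediation model.

Five comparator strategies are implemented as scikit-learn style
estimators sharing one interface: ``fit(U, M, Y, C=None)`` with fitted
``effects_`` (a :class:`~lcmediate.mediation.MediationEffects`).

* ``ModalAssignmentMediation`` -- assign everyone to their most likely
  class and ignore the misclassification (classify-analyze).
* ``BCHMediation`` -- modal assignment followed by the modified BCH
  correction: each person is expanded into k pseudo-rows weighted by the
  inverse classification-error matrix (weights may be negative).
* ``NonInclusivePCD`` (nPCD) -- multiply impute class membership from the
  unconditional posterior and pool by Rubin's rules.
* ``InclusivePCD`` (incPCD) -- as nPCD but the posterior comes from a
  conditional latent class model with M and Y (and confounders) as
  covariates predicting membership.
* ``OneStepMediation`` -- joint maximum likelihood of the measurement and
  structural models, so the mediator and outcome act as additional class
  indicators and class-derivation uncertainty propagates into the
  effects.

The iterative updated-pseudo-class-draws estimator lives in
:mod:`lcmediate.upcd`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess2

from .lca import (
    MISSING,
    BinaryLCA,
    CovariateLCA,
    ConvergenceWarning,
    _compress,
    _pattern_loglik,
    classification_matrix,
    encode_indicators,
    modal_assign,
)
from .mediation import (
    MediationEffects,
    StructuralParams,
    fit_structural,
    fit_structural_fast,
    mediation_effects,
    mediator_design,
    outcome_design,
)

__all__ = [
    "PooledEstimate",
    "rubin_pool",
    "bch_weights",
    "ModalAssignmentMediation",
    "BCHMediation",
    "NonInclusivePCD",
    "InclusivePCD",
    "OneStepMediation",
    "run_modal",
    "run_bch",
    "run_npcd",
    "run_incpcd",
    "run_onestep",
    "EmptyClassError",
]


class EmptyClassError(RuntimeError):
    """An imputed draw or fit left a latent class with no members."""


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------


@dataclass
class PooledEstimate:
    """A multiply-imputed estimate pooled by Rubin's rules."""

    estimate: float
    within_var: float
    between_var: float
    total_se: float
    m: int
    mc_error: float


def rubin_pool(per_draw_estimates, per_draw_variances) -> PooledEstimate:
    """Pool m imputation-specific estimates and variances.

    Total variance = mean within-draw variance + (1 + 1/m) x between-draw
    variance; the Monte Carlo error of the pooled point estimate is
    sqrt(between / m), used to verify that the number of imputations
    keeps the Monte Carlo error below 10% of the pooled SE.
    """
    est = np.asarray(per_draw_estimates, dtype=float)
    var = np.asarray(per_draw_variances, dtype=float)
    m = len(est)
    if m < 1 or len(var) != m:
        raise ValueError("need matching, non-empty estimate and variance vectors")
    between = float(np.var(est, ddof=1)) if m > 1 else 0.0
    within = float(np.mean(var))
    total = within + (1.0 + 1.0 / m) * between
    return PooledEstimate(
        float(np.mean(est)), within, between, float(np.sqrt(total)), m,
        float(np.sqrt(between / m)),
    )


def _pool_effects(per_draw: list[MediationEffects], class_names) -> MediationEffects:
    est = np.stack([e.estimates for e in per_draw])  # (m, k-1, 3)
    var = np.stack([e.ses for e in per_draw]) ** 2
    m = len(per_draw)
    shape = est.shape[1:]
    pooled_est = np.empty(shape)
    pooled_se = np.empty(shape)
    mc_err = np.empty(shape)
    for idx in np.ndindex(*shape):
        p = rubin_pool(est[(slice(None), *idx)], var[(slice(None), *idx)])
        pooled_est[idx], pooled_se[idx], mc_err[idx] = p.estimate, p.total_se, p.mc_error
    out = MediationEffects(pooled_est, pooled_se, list(class_names))
    out.diagnostics["m"] = m
    out.diagnostics["mc_error"] = mc_err
    with np.errstate(divide="ignore", invalid="ignore"):
        out.diagnostics["mc_error_ratio"] = np.where(pooled_se > 0, mc_err / pooled_se, 0.0)
    return out


# ---------------------------------------------------------------------------
# BCH weights
# ---------------------------------------------------------------------------


def bch_weights(D: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Inverse classification-error weights for the modified BCH estimator.

    Person i with modal class w receives weight ``inv(D)[w, x]`` for
    pseudo-group x.  Rows of the weight array sum to one; weights may be
    negative and are retained as such.
    """
    D = np.asarray(D, dtype=float)
    cond = np.linalg.cond(D)
    if cond > 1e8:
        warnings.warn(
            f"classification matrix nearly singular (cond={cond:.2e}); "
            "BCH correction is unreliable at this separation level",
            ConvergenceWarning,
        )
    Dinv = np.linalg.inv(D)
    return Dinv[np.asarray(W)]


# ---------------------------------------------------------------------------
# shared estimator plumbing
# ---------------------------------------------------------------------------


class _LinkingBase(BaseEstimator):
    """Shared fit plumbing: unconditional LCA, alignment, seeding."""

    _method = ""

    def __init__(
        self,
        n_classes: int = 4,
        n_restarts: int = 20,
        tol: float = 1e-8,
        max_iter: int = 5000,
        reference_profiles=None,
        class_names=None,
        firth_on_separation: bool = True,
        random_state: int | None = None,
    ):
        self.n_classes = n_classes
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.reference_profiles = reference_profiles
        self.class_names = class_names
        self.firth_on_separation = firth_on_separation
        self.random_state = random_state

    def _names(self):
        return list(self.class_names) if self.class_names is not None else [
            f"class{i + 1}" for i in range(self.n_classes)
        ]

    def _seed_seq(self):
        return np.random.SeedSequence(self.random_state)

    def _fit_lca(self, U, seed) -> BinaryLCA:
        lca = BinaryLCA(
            n_classes=self.n_classes,
            n_restarts=self.n_restarts,
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=seed,
        ).fit(U)
        lca.align(self.reference_profiles)
        return lca

    @staticmethod
    def _conf(C, n):
        if C is None:
            return None
        C = np.asarray(C, dtype=float)
        C = C.reshape(n, -1)
        if not np.all(np.isfinite(C)):
            raise ValueError("confounders must be complete")
        return C

    def _effects(self, W, M, Y, C, weights=None) -> MediationEffects:
        sp = fit_structural(
            W, M, Y, self.n_classes, C, weights, self.firth_on_separation
        )
        eff = mediation_effects(sp, C_rows=C, class_names=self._names())
        eff.method = self._method
        eff.diagnostics["fit_method"] = sp.fit_method
        self.structural_ = sp
        return eff


def _multinomial_draw(post: np.ndarray, rng) -> np.ndarray:
    """One class label per row of a posterior matrix."""
    cum = np.cumsum(post, axis=1)
    u = rng.random(len(post)) * cum[:, -1]
    return (u[:, None] >= cum).sum(axis=1)


class ModalAssignmentMediation(_LinkingBase):
    """Classify-analyze: modal class assignment with no correction.

    Biased toward the null unless class separation is excellent, because
    classification error in the assigned classes is ignored.
    """

    _method = "modal"

    def fit(self, U, M, Y, C=None, lca: BinaryLCA | None = None):
        M, Y = np.asarray(M), np.asarray(Y)
        C = self._conf(C, len(M))
        seed = self._seed_seq().generate_state(1)[0]
        self.lca_ = lca if lca is not None else self._fit_lca(U, seed)
        W = self.lca_.predict(U)
        self.effects_ = self._effects(W, M, Y, C)
        return self


class BCHMediation(_LinkingBase):
    """Modified BCH bias-adjusted three-step estimator.

    A weighted multiple-group analysis: everyone enters each pseudo-class
    with the inverse classification-error weight, undoing the modal
    misclassification in expectation.  Negative weights are retained.
    """

    _method = "bch"

    def fit(self, U, M, Y, C=None, lca: BinaryLCA | None = None):
        M, Y = np.asarray(M), np.asarray(Y)
        n = len(M)
        C = self._conf(C, n)
        seed = self._seed_seq().generate_state(1)[0]
        self.lca_ = lca if lca is not None else self._fit_lca(U, seed)
        post = self.lca_.predict_proba(U)
        D = classification_matrix(post)
        self.classification_matrix_ = D
        W = modal_assign(post)
        h = bch_weights(D, W)  # (n, k)
        k = self.n_classes
        # person-major expansion: person i occupies rows i*k .. i*k+k-1
        Wx = np.repeat(np.arange(k)[None, :], n, axis=0).ravel()
        wts = h.ravel()
        Cx = None if C is None else np.repeat(C, k, axis=0)
        Mx = np.repeat(M, k).astype(float)
        Yx = np.repeat(Y, k).astype(float)
        self.effects_ = self._effects(Wx, Mx, Yx, Cx, weights=wts)
        return self


class NonInclusivePCD(_LinkingBase):
    """Non-inclusive pseudo class draws (nPCD).

    Class membership is multiply imputed from the unconditional
    posterior P(X | U); because the posterior ignores the mediator and
    outcome, estimates suffer omitted-outcome attenuation that worsens as
    entropy falls.
    """

    _method = "npcd"

    def __init__(
        self,
        n_classes: int = 4,
        n_draws: int = 40,
        n_restarts: int = 20,
        tol: float = 1e-8,
        max_iter: int = 5000,
        reference_profiles=None,
        class_names=None,
        firth_on_separation: bool = True,
        random_state: int | None = None,
    ):
        super().__init__(
            n_classes=n_classes,
            n_restarts=n_restarts,
            tol=tol,
            max_iter=max_iter,
            reference_profiles=reference_profiles,
            class_names=class_names,
            firth_on_separation=firth_on_separation,
            random_state=random_state,
        )
        self.n_draws = n_draws

    def _posterior(self, U, M, Y, C, seed):
        self.lca_ = self._prefit if self._prefit is not None else self._fit_lca(U, seed)
        return self.lca_.predict_proba(U)

    def fit(self, U, M, Y, C=None, lca=None):
        M, Y = np.asarray(M), np.asarray(Y)
        C = self._conf(C, len(M))
        self._prefit = lca
        ss = self._seed_seq()
        lca_seed = ss.generate_state(1)[0]
        post = self._posterior(U, M, Y, C, lca_seed)
        per_draw = []
        redraws = 0
        draw_streams = ss.spawn(self.n_draws)
        for d in range(self.n_draws):
            rng = np.random.default_rng(draw_streams[d])
            for attempt in range(20):
                W = _multinomial_draw(post, rng)
                if len(np.unique(W)) == self.n_classes:
                    break
                redraws += 1
            else:
                raise EmptyClassError("could not draw a complete set of classes")
            if C is None:
                sp = fit_structural_fast(W, M, Y, self.n_classes, self.firth_on_separation)
            else:
                sp = fit_structural(
                    W, M, Y, self.n_classes, C,
                    firth_on_separation=self.firth_on_separation,
                )
            eff = mediation_effects(sp, C_rows=C, class_names=self._names())
            per_draw.append(eff)
        self.effects_ = _pool_effects(per_draw, self._names())
        self.effects_.method = self._method
        self.effects_.diagnostics["redraws"] = redraws
        self.per_draw_ = per_draw
        return self


class InclusivePCD(NonInclusivePCD):
    """Inclusive pseudo class draws (incPCD).

    The class-derivation model is a conditional latent class model with
    the mediator, outcome and any confounders as covariates predicting
    membership, so the imputation posterior P(X | U, M, Y, C) conditions
    on everything in the analysis model.  The exposure-mediator
    interaction is not representable in this structural model, which is
    the method's known compatibility gap.
    """

    _method = "incpcd"

    def _posterior(self, U, M, Y, C, seed):
        Z = np.column_stack([M, Y]) if C is None else np.column_stack([M, Y, C])
        self.lca_ = CovariateLCA(
            n_classes=self.n_classes,
            n_restarts=self.n_restarts,
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=seed,
        ).fit(U, Z)
        self.lca_.align(self.reference_profiles)
        return self.lca_.predict_proba(U, Z)


# ---------------------------------------------------------------------------
# one-step joint maximum likelihood
# ---------------------------------------------------------------------------


def _permute_structural(alpha, beta, perm, k, n_conf):
    """Re-express (alpha, beta) after a class relabeling."""
    perm = np.asarray(perm)
    la = np.concatenate([alpha[0] + alpha[1:k], [alpha[0]]])  # per-class M logits
    la = la[perm]
    alpha_new = np.concatenate([[la[-1]], la[:-1] - la[-1], alpha[k:]])
    ly0 = np.concatenate([beta[0] + beta[2 : 1 + k], [beta[0]]])
    ly1_slope = np.concatenate([beta[1] + beta[1 + k : 2 * k], [beta[1]]])
    ly0, ly1_slope = ly0[perm], ly1_slope[perm]
    beta_new = np.concatenate(
        [[ly0[-1], ly1_slope[-1]], ly0[:-1] - ly0[-1], ly1_slope[:-1] - ly1_slope[-1],
         beta[2 * k:]]
    )
    return alpha_new, beta_new


class OneStepMediation(_LinkingBase):
    """Joint ML of the latent class measurement and mediation models.

    One EM run estimates (pi, tau, alpha, beta) simultaneously; the
    posterior conditions on (U, M, Y), and the joint observed-information
    covariance propagates class-derivation uncertainty into the
    delta-method effect SEs.
    """

    _method = "onestep"

    def fit(self, U, M, Y, C=None):
        enc = encode_indicators(U)
        M = np.asarray(M, dtype=float)
        Y = np.asarray(Y, dtype=float)
        n = len(M)
        C = self._conf(C, n)
        k = self.n_classes
        nc = 0 if C is None else C.shape[1]

        cols = [enc.astype(float), M[:, None], Y[:, None]]
        if C is not None:
            cols.append(C)
        joint = np.column_stack(cols)
        _, first, inverse, counts = np.unique(
            joint, axis=0, return_index=True, return_inverse=True, return_counts=True
        )
        inverse = inverse.ravel()
        patterns = enc[first]
        Ms, Ys = M[first], Y[first]
        Cs = None if C is None else C[first]
        counts = counts.astype(float)
        S = len(patterns)

        classes = np.arange(k)
        Wx = np.repeat(classes[None, :], S, axis=0).ravel()  # pattern-major
        Msx = np.repeat(Ms, k)
        Csx = None if Cs is None else np.repeat(Cs, k, axis=0)
        Xa = mediator_design(Wx, k, Csx)
        Xb = outcome_design(Wx, Msx, k, Csx)
        Ma = np.repeat(Ms, k)
        Yb = np.repeat(Ys, k)

        def e_step(pi, probs, alpha, beta):
            pm = expit(Xa @ alpha).reshape(S, k)
            py = expit(Xb @ beta).reshape(S, k)
            L = _pattern_loglik(patterns, probs) + np.log(np.maximum(pi, 1e-300))
            L = L + np.where(Ms[:, None] == 1, np.log(pm), np.log1p(-pm))
            L = L + np.where(Ys[:, None] == 1, np.log(py), np.log1p(-py))
            norm = logsumexp(L, axis=1)
            return np.exp(L - norm[:, None]), float(counts @ norm)

        from .glm import fit_logistic

        def m_step(resp, alpha0, beta0):
            cw = counts[:, None] * resp
            pi = cw.sum(axis=0) / counts.sum()
            ones = (patterns == 1).astype(float)
            obs = (patterns != MISSING).astype(float)
            probs = np.clip(
                (cw.T @ ones) / np.maximum(cw.T @ obs, 1e-300), 1e-6, 1 - 1e-6
            )
            w = cw.ravel()
            fa = fit_logistic(Xa, Ma, w, firth_on_separation=False, max_iter=5,
                              start=alpha0)
            fb = fit_logistic(Xb, Yb, w, firth_on_separation=False, max_iter=5,
                              start=beta0)
            return pi, probs, fa.coef, fb.coef

        from .lca import _random_responsibilities

        rng = np.random.default_rng(self._seed_seq().generate_state(1)[0])
        best = None
        for _ in range(max(1, self.n_restarts)):
            resp = _random_responsibilities(rng, S, k)
            alpha = np.zeros(k + nc)
            beta = np.zeros(2 * k + nc)
            ll_old, trace = -np.inf, []
            for _ in range(min(100, self.max_iter)):
                pi, probs, alpha, beta = m_step(resp, alpha, beta)
                resp, ll = e_step(pi, probs, alpha, beta)
                trace.append(ll)
                if ll - ll_old < self.tol * (abs(ll_old) + 1.0) and len(trace) > 1:
                    break
                ll_old = ll
            if best is None or ll > best[0]:
                best = (ll, resp, pi, probs, alpha, beta, trace)
        ll, resp, pi, probs, alpha, beta, trace = best
        ll_old = ll
        converged = False
        for _ in range(self.max_iter):
            pi, probs, alpha, beta = m_step(resp, alpha, beta)
            resp, ll = e_step(pi, probs, alpha, beta)
            trace.append(ll)
            if ll - ll_old < self.tol * (abs(ll_old) + 1.0):
                converged = True
                break
            ll_old = ll
        if not converged:
            warnings.warn("one-step EM did not converge", ConvergenceWarning)
        self.converged_ = converged
        self.loglik_ = ll
        self.loglik_trace_ = trace

        # align labels, re-expressing structural coefficients
        if self.reference_profiles is not None:
            from .lca import align_permutation

            perm = align_permutation(probs, np.asarray(self.reference_profiles))
        else:
            perm = np.argsort(pi, kind="stable")
        pi, probs = pi[perm], probs[perm]
        alpha, beta = _permute_structural(alpha, beta, perm, k, nc)
        self.class_weights_, self.item_probs_ = pi, probs
        self.alpha_, self.beta_ = alpha, beta

        # joint observed-information covariance
        p = probs.shape[1]
        theta = np.concatenate(
            [np.log(pi[:-1] / pi[-1]), np.log(probs / (1 - probs)).ravel(), alpha, beta]
        )
        n_meas = (k - 1) + k * p

        def negfree_ll(th):
            gamma = np.concatenate([th[: k - 1], [0.0]])
            pii = np.exp(gamma - logsumexp(gamma))
            pr = expit(th[k - 1 : n_meas].reshape(k, p))
            a = th[n_meas : n_meas + k + nc]
            b = th[n_meas + k + nc :]
            _, llv = e_step(pii, np.clip(pr, 1e-12, 1 - 1e-12), a, b)
            return llv

        hess = approx_hess2(theta, negfree_ll)
        info = -(hess + hess.T) / 2.0
        boundary = ((probs <= 2e-6) | (probs >= 1 - 2e-6)).ravel()
        free = np.ones(len(theta), dtype=bool)
        free[k - 1 : n_meas] = ~boundary  # clamped thresholds held fixed
        from .lca import _invert_information

        cov, se_all, floored_load = _invert_information(info, free)
        self.covariance_ = cov
        self.boundary_thresholds_ = boundary
        tau_se = se_all[k - 1 : n_meas]
        self.max_threshold_se_ = (
            float(np.nanmax(tau_se)) if np.any(np.isfinite(tau_se)) else np.nan
        )
        self.se_inflated_ = bool(
            np.any(se_all[np.isfinite(se_all)] > 25.0) or np.any(floored_load)
        )

        sp = StructuralParams(
            alpha,
            beta,
            cov[n_meas : n_meas + k + nc, n_meas : n_meas + k + nc],
            cov[n_meas + k + nc :, n_meas + k + nc :],
            k,
            nc,
            "ML",
        )
        sp_full_cov = cov[n_meas:, n_meas:]
        eff = mediation_effects(sp, C_rows=C, class_names=self._names(), se=False)
        # delta method with the full (alpha, beta) joint covariance block
        from .mediation import _effects_vector

        th_ab = sp.theta()
        q = len(th_ab)
        grad = np.empty((eff.estimates.size, q))
        for j in range(q):
            h = 1e-5 * max(1.0, abs(th_ab[j]))
            tp, tm = th_ab.copy(), th_ab.copy()
            tp[j] += h
            tm[j] -= h
            grad[:, j] = (
                _effects_vector(tp, k, nc, C) - _effects_vector(tm, k, nc, C)
            ) / (2 * h)
        var = np.einsum("iq,qr,ir->i", grad, sp_full_cov, grad)
        eff.ses = np.sqrt(np.clip(var, 0, None)).reshape(k - 1, 3)
        eff.method = self._method
        self.structural_ = sp
        self.effects_ = eff
        return self


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------


def run_modal(U, M, Y, C=None, k=4, seed=None, **kw) -> MediationEffects:
    return ModalAssignmentMediation(n_classes=k, random_state=seed, **kw).fit(
        U, M, Y, C
    ).effects_


def run_bch(U, M, Y, C=None, k=4, seed=None, **kw) -> MediationEffects:
    return BCHMediation(n_classes=k, random_state=seed, **kw).fit(U, M, Y, C).effects_


def run_npcd(U, M, Y, C=None, k=4, m=40, seed=None, **kw) -> MediationEffects:
    return NonInclusivePCD(n_classes=k, n_draws=m, random_state=seed, **kw).fit(
        U, M, Y, C
    ).effects_


def run_incpcd(U, M, Y, C=None, k=4, m=40, seed=None, **kw) -> MediationEffects:
    return InclusivePCD(n_classes=k, n_draws=m, random_state=seed, **kw).fit(
        U, M, Y, C
    ).effects_


def run_onestep(U, M, Y, C=None, k=4, n_restarts=20, seed=None, **kw) -> MediationEffects:
    return OneStepMediation(
        n_classes=k, n_restarts=n_restarts, random_state=seed, **kw
    ).fit(U, M, Y, C).effects_
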