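"""Latent class analysis for binary indicators.

`BinaryLCA` fits an unconditional finite-mixture model for p binary
indicators assumed mutually independent given class membership:

    P(U | X=x) = prod_j p_xj^{u_j} (1 - p_xj)^{1-u_j},   P(X=x) = pi_x

by EM with random-responsibility restarts.  Missing indicator cells are
handled by full-information maximum likelihood (each row contributes its
observed cells only).  `CovariateLCA` adds a multinomial-logit structural
model P(X=x | z) = softmax(gamma_x + delta_x' z), used by the inclusive
pseudo-class-draw estimator where the mediator and outcome predict class
membership.

Parameters live on the logit scale: class logits gamma (reference class
last, fixed at 0) and item thresholds tau with P(U_j=1|X=x) =
expit(tau_xj).  The joint sampling covariance of (gamma, tau) is obtained
from the numerically differentiated observed-data information.

Rows with identical observed indicator patterns share posteriors, so all
heavy computation is done on the (at most 3^p) distinct patterns, which
makes n = 10^6 routine.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit, logsumexp
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess2

__all__ = [
    "BinaryLCA",
    "CovariateLCA",
    "relative_entropy",
    "classification_matrix",
    "modal_assign",
    "align_permutation",
    "DegenerateFitError",
    "ConvergenceWarning",
]

MISSING = 2  # internal code for a missing indicator cell


class DegenerateFitError(ValueError):
    """More classes requested than distinct response patterns."""


class ConvergenceWarning(UserWarning):
    pass


def encode_indicators(U) -> np.ndarray:
    """Encode an n x p indicator table as int8 {0, 1, 2=missing}.

    Accepts a DataFrame or array with entries 0/1 and NaN/NA for missing.
    Every non-missing entry must be exactly 0 or 1 and every row must
    retain at least one observed indicator.
    """
    arr = np.asarray(U, dtype=float)
    if arr.ndim != 2:
        raise ValueError("indicator table must be 2-dimensional")
    enc = np.full(arr.shape, MISSING, dtype=np.int8)
    obs = np.isfinite(arr)
    vals = arr[obs]
    if not np.all((vals == 0.0) | (vals == 1.0)):
        raise ValueError("non-missing indicator entries must be exactly 0 or 1")
    enc[obs] = vals.astype(np.int8)
    if np.any((enc == MISSING).all(axis=1)):
        raise ValueError("each row must have at least one observed indicator")
    return enc


def _compress(enc: np.ndarray):
    """Distinct response patterns, row->pattern index, and counts."""
    patterns, inverse, counts = np.unique(
        enc, axis=0, return_inverse=True, return_counts=True
    )
    return patterns, inverse.ravel(), counts.astype(float)


def _pattern_loglik(patterns: np.ndarray, item_probs: np.ndarray) -> np.ndarray:
    """(S, k) log P(pattern | class) over observed cells only."""
    lp = np.log(item_probs)  # (k, p)
    lq = np.log1p(-item_probs)
    ones = (patterns == 1).astype(float)
    zeros = (patterns == 0).astype(float)
    return ones @ lp.T + zeros @ lq.T


def relative_entropy(post: np.ndarray) -> float:
    """Relative entropy of a posterior matrix, in [0, 1].

    1 - sum_i sum_x (-p_ix ln p_ix) / (n ln k); 1 means perfectly
    separated classes, 0 means uniformly uncertain assignment.
    """
    post = np.asarray(post, dtype=float)
    n, k = post.shape
    if k < 2:
        raise ValueError("relative entropy requires at least two classes")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(post > 0, post * np.log(post), 0.0)
    return float(1.0 + plogp.sum() / (n * np.log(k)))


def modal_assign(post: np.ndarray) -> np.ndarray:
    """Most likely class per row; ties resolved to the lowest class index."""
    return np.argmax(post, axis=1)


def classification_matrix(post: np.ndarray, assignment: str = "modal") -> np.ndarray:
    """D[x, w] = P(assigned class W=w | true class X=x).

    Estimated from the posterior matrix as the posterior-weighted share of
    modal assignments, so rows sum to one.  One-hot posteriors give the
    identity matrix.
    """
    if assignment != "modal":
        raise ValueError("only modal assignment is supported")
    post = np.asarray(post, dtype=float)
    n, k = post.shape
    W = modal_assign(post)
    D = np.zeros((k, k))
    for w in range(k):
        D[:, w] = post[W == w].sum(axis=0)
    denom = D.sum(axis=1, keepdims=True)
    if np.any(denom <= 0):
        raise ValueError("degenerate class: zero total posterior mass")
    return D / denom


def align_permutation(item_probs: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Permutation aligning fitted classes to reference item-probability rows.

    Minimizes the total absolute difference between item-probability
    profiles over all k! permutations (k is small here).
    """
    k = item_probs.shape[0]
    best, best_cost = None, np.inf
    for perm in itertools.permutations(range(k)):
        cost = np.abs(item_probs[list(perm)] - reference).sum()
        if cost < best_cost:
            best, best_cost = perm, cost
    return np.asarray(best)


def _random_responsibilities(rng, S: int, k: int) -> np.ndarray:
    """Sharp Dirichlet(0.2) responsibility draws per response pattern.

    Near-one-hot rows act like a random partition of the patterns, which
    escapes the class-merging local optima that flat random starts fall
    into when indicators are strongly class-determined.
    """
    resp = rng.gamma(0.2, size=(S, k)) + 1e-12
    return resp / resp.sum(axis=1, keepdims=True)


def _invert_information(info: np.ndarray, free: np.ndarray):
    """Invert an observed information over its free parameters.

    Rows/columns of fixed (boundary) parameters are excluded; their
    variance entries are zero and their SEs reported as NaN.  Residual
    non-positive eigenvalues among the free block are floored, and
    parameters loading mostly on floored directions are flagged.
    """
    q = len(free)
    sub = info[np.ix_(free, free)]
    eigval, eigvec = np.linalg.eigh((sub + sub.T) / 2.0)
    floor = max(1e-10, 1e-12 * max(eigval.max(), 1.0)) if len(eigval) else 1.0
    floored = eigval < floor
    eigval = np.maximum(eigval, floor)
    cov_sub = (eigvec / eigval) @ eigvec.T
    cov = np.zeros((q, q))
    cov[np.ix_(free, free)] = (cov_sub + cov_sub.T) / 2.0
    se = np.full(q, np.nan)
    se[free] = np.sqrt(np.clip(np.diag(cov_sub), 0.0, None))
    floored_load = np.zeros(q, dtype=bool)
    if np.any(floored):
        load = (eigvec[:, floored] ** 2).sum(axis=1)
        floored_load[free] = load > 0.5
    return cov, se, floored_load


@dataclass
class ParamCovariance:
    """Sampling covariance of the stacked (gamma, tau) parameters."""

    cov: np.ndarray
    se: np.ndarray
    inflated: np.ndarray  # boolean flag per parameter
    max_threshold_se: float
    se_inflated: bool = False  # dataset-level flag feeding the exclusion rule


class BinaryLCA(BaseEstimator):
    """Unconditional latent class model for binary indicators.

    Parameters
    ----------
    n_classes : number of latent classes k.
    n_restarts : random-responsibility EM restarts.  Every restart is run
        for ``n_init_iter`` iterations and only the best is run to full
        convergence.
    tol : relative log-likelihood change declaring convergence.
    max_iter : EM iteration cap for the final run.
    clamp : item probabilities are kept in [clamp, 1-clamp] so thresholds
        stay finite; parameters at the clamp are flagged as boundary
        estimates.
    random_state : seed for restart initialization.

    Attributes
    ----------
    class_weights_ : (k,) mixing proportions pi.
    item_probs_ : (k, p) class-specific response probabilities.
    class_logits_, item_logits_ : the same on the logit scale (gamma has
        length k-1; the last class is the reference).
    loglik_, loglik_trace_, n_iter_, converged_ : fit diagnostics.
    """

    def __init__(
        self,
        n_classes: int = 4,
        n_restarts: int = 20,
        tol: float = 1e-8,
        max_iter: int = 5000,
        n_init_iter: int = 100,
        clamp: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_classes = n_classes
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.n_init_iter = n_init_iter
        self.clamp = clamp
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _m_step_measurement(self, patterns, counts, resp):
        cw = counts[:, None] * resp  # (S, k)
        pi = cw.sum(axis=0) / counts.sum()
        ones = (patterns == 1).astype(float)
        obs = (patterns != MISSING).astype(float)
        num = cw.T @ ones
        den = cw.T @ obs
        probs = np.where(den > 0, num / np.maximum(den, 1e-300), 0.5)
        return pi, np.clip(probs, self.clamp, 1.0 - self.clamp)

    def _e_step(self, patterns, log_prior):
        # log_prior: (k,) or (S, k)
        L = _pattern_loglik(patterns, self.item_probs_) + log_prior
        norm = logsumexp(L, axis=1)
        return np.exp(L - norm[:, None]), norm

    def _run_em(self, patterns, counts, resp, n_iter, trace):
        ll_old = -np.inf
        it = 0
        for it in range(n_iter):
            pi, probs = self._m_step_measurement(patterns, counts, resp)
            self.class_weights_, self.item_probs_ = pi, probs
            resp, norm = self._e_step(patterns, np.log(np.maximum(pi, 1e-300)))
            ll = float(counts @ norm)
            trace.append(ll)
            if ll - ll_old < self.tol * (abs(ll_old) + 1.0) and it > 0:
                return resp, ll, True, it + 1
            ll_old = ll
        return resp, ll_old, False, it + 1

    # -- API ---------------------------------------------------------------

    def fit(self, U, y=None):
        enc = encode_indicators(U)
        k = self.n_classes
        if k < 1:
            raise ValueError("n_classes must be >= 1")
        if enc.shape[0] < k:
            raise ValueError("need at least as many rows as classes")
        patterns, inverse, counts = _compress(enc)
        if len(patterns) < k:
            raise DegenerateFitError(
                f"{k} classes requested but only {len(patterns)} distinct patterns"
            )
        self._patterns_, self._inverse_, self._counts_ = patterns, inverse, counts
        self.n_features_in_ = enc.shape[1]

        if k == 1:
            # closed form: independent Bernoulli per item
            obs = patterns != MISSING
            ones = (patterns == 1).astype(float)
            den = counts @ obs
            probs = np.clip((counts @ ones) / den, self.clamp, 1.0 - self.clamp)
            self.class_weights_ = np.array([1.0])
            self.item_probs_ = probs[None, :]
            _, norm = self._e_step(patterns, np.zeros(1))
            self.loglik_ = float(counts @ norm)
            self.loglik_trace_ = [self.loglik_]
            self.converged_, self.n_iter_ = True, 0
            self._finalize()
            return self

        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_restarts)):
            resp0 = _random_responsibilities(rng, len(patterns), k)
            trace: list[float] = []
            resp, ll, conv, _ = self._run_em(
                patterns, counts, resp0, min(self.n_init_iter, self.max_iter), trace
            )
            state = (ll, resp, self.class_weights_, self.item_probs_, trace)
            if best is None or ll > best[0]:
                best = state
        ll, resp, self.class_weights_, self.item_probs_, trace = best
        resp, ll, conv, extra = self._run_em(patterns, counts, resp, self.max_iter, trace)
        self.loglik_ = ll
        self.loglik_trace_ = trace
        self.converged_ = conv
        self.n_iter_ = len(trace)
        if not conv:
            warnings.warn(
                "EM did not converge within max_iter on any restart",
                ConvergenceWarning,
            )
        self._finalize()
        return self

    def _finalize(self):
        k = self.n_classes
        pi = np.maximum(self.class_weights_, 1e-300)
        self.class_logits_ = np.log(pi[:-1]) - np.log(pi[-1]) if k > 1 else np.zeros(0)
        self.item_logits_ = logit(self.item_probs_)
        self.n_params_ = (k - 1) + k * self.item_probs_.shape[1]
        self.covariance_ = None

    def reorder(self, perm: np.ndarray) -> "BinaryLCA":
        """Relabel classes in the given order (in place)."""
        perm = np.asarray(perm)
        self.class_weights_ = self.class_weights_[perm]
        self.item_probs_ = self.item_probs_[perm]
        self._finalize()
        return self

    def align(self, reference_profiles: np.ndarray | None = None) -> "BinaryLCA":
        """Align class labels, resolving label switching.

        With reference profiles (e.g. the generating item probabilities),
        classes are permuted to minimize the total absolute difference of
        item-probability profiles.  Without, classes are ordered by
        ascending size so the largest class is last and serves as the
        reference level of the structural models.
        """
        if reference_profiles is None:
            perm = np.argsort(self.class_weights_, kind="stable")
        else:
            perm = align_permutation(self.item_probs_, np.asarray(reference_profiles))
        return self.reorder(perm)

    def predict_proba(self, U) -> np.ndarray:
        """Posterior class-assignment probabilities P(X=x | U)."""
        enc = encode_indicators(U)
        patterns, inverse, _ = _compress(enc)
        L = _pattern_loglik(patterns, self.item_probs_) + np.log(
            np.maximum(self.class_weights_, 1e-300)
        )
        post = np.exp(L - logsumexp(L, axis=1)[:, None])
        return post[inverse]

    def predict(self, U) -> np.ndarray:
        return modal_assign(self.predict_proba(U))

    def score(self, U, y=None) -> float:
        """Average observed-data log-likelihood per row."""
        enc = encode_indicators(U)
        patterns, inverse, _ = _compress(enc)
        L = _pattern_loglik(patterns, self.item_probs_) + np.log(
            np.maximum(self.class_weights_, 1e-300)
        )
        return float(np.mean(logsumexp(L, axis=1)[inverse]))

    # -- covariance --------------------------------------------------------

    def _theta(self) -> np.ndarray:
        return np.concatenate([self.class_logits_, self.item_logits_.ravel()])

    def _loglik_at(self, theta: np.ndarray, patterns, counts) -> float:
        k, p = self.n_classes, self.item_probs_.shape[1]
        gamma = np.concatenate([theta[: k - 1], [0.0]])
        log_pi = gamma - logsumexp(gamma)
        probs = expit(theta[k - 1 :].reshape(k, p))
        L = _pattern_loglik(patterns, np.clip(probs, 1e-12, 1 - 1e-12)) + log_pi
        return float(counts @ logsumexp(L, axis=1))

    def estimate_covariance(self, U=None, se_inflation_threshold: float = 25.0) -> ParamCovariance:
        """Observed-information covariance of (gamma, tau).

        The Hessian of the observed-data log-likelihood is computed by
        central finite differences at the estimate; the information matrix
        is inverted after flooring non-positive eigenvalues, and
        parameters whose SE exceeds ``se_inflation_threshold`` on the
        logit scale, or whose item probability sits at the clamp
        boundary, are flagged as inflated.  Flagged thresholds feed the
        simulation-study exclusion rule.
        """
        if U is not None:
            enc = encode_indicators(U)
            patterns, _, counts = _compress(enc)
        else:
            patterns, counts = self._patterns_, self._counts_
        theta = self._theta()
        hess = approx_hess2(theta, self._loglik_at, args=(patterns, counts))
        info = -(hess + hess.T) / 2.0
        k = self.n_classes
        boundary = (
            (self.item_probs_ <= 2 * self.clamp)
            | (self.item_probs_ >= 1.0 - 2 * self.clamp)
        ).ravel()
        # parameters at the clamp boundary carry no usable curvature; they
        # are held fixed (profiled out) and flagged rather than inverted
        free = np.ones(len(theta), dtype=bool)
        free[k - 1 :] = ~boundary
        cov, se, floored_load = _invert_information(info, free)
        inflated = se > se_inflation_threshold
        inflated[k - 1 :] |= boundary
        inflated |= floored_load
        tau_se = se[k - 1 :]
        max_tau = float(np.nanmax(tau_se)) if np.any(np.isfinite(tau_se)) else np.nan
        se_inflated = bool(
            np.any(se[np.isfinite(se)] > se_inflation_threshold) or np.any(floored_load)
        )
        out = ParamCovariance(cov, se, inflated, max_tau, se_inflated)
        self.covariance_ = out
        return out


class CovariateLCA(BinaryLCA):
    """Latent class model with covariates predicting class membership.

    The measurement model is unchanged; class membership follows a
    multinomial-logit structural model softmax(gamma_x + delta_x' z) with
    the last class as reference.  Posteriors condition on the covariates
    as well as the indicators.  Covariates must be complete.
    """

    def fit(self, U, Z, y=None):
        enc = encode_indicators(U)
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[0] != enc.shape[0]:
            Z = Z.T
        if Z.shape[0] != enc.shape[0]:
            raise ValueError("covariates and indicators have different lengths")
        if not np.all(np.isfinite(Z)):
            raise ValueError("covariates must be complete (no missing values)")
        k = self.n_classes
        # compress over joint (U, Z) rows; discrete covariates keep S small
        joint = np.column_stack([enc.astype(float), Z])
        _, first, inverse, counts = np.unique(
            joint, axis=0, return_index=True, return_inverse=True, return_counts=True
        )
        inverse = inverse.ravel()
        patterns = enc[first]
        Zs = Z[first]
        counts = counts.astype(float)

        self._patterns_, self._inverse_, self._counts_ = patterns, inverse, counts
        self._Zs_ = Zs
        self.n_features_in_ = enc.shape[1]
        if len(patterns) < k:
            raise DegenerateFitError("fewer distinct joint patterns than classes")

        rng = np.random.default_rng(self.random_state)
        nz = Zs.shape[1]
        best = None
        for _ in range(max(1, self.n_restarts)):
            resp0 = _random_responsibilities(rng, len(patterns), k)
            state = self._run_conditional_em(
                patterns, Zs, counts, resp0, min(self.n_init_iter, self.max_iter),
                n_newton=1,
            )
            if best is None or state[0] > best[0]:
                best = state
        ll, resp, coefs, probs, trace = best
        self.item_probs_, self._struct_coefs_ = probs, coefs
        state = self._run_conditional_em(
            patterns, Zs, counts, resp, self.max_iter, coefs, trace, n_newton=3
        )
        ll, resp, coefs, probs, trace = state
        self.item_probs_ = probs
        self._struct_coefs_ = coefs  # (k-1, 1+nz): intercept then covariate slopes
        self.loglik_ = ll
        self.loglik_trace_ = trace
        self.n_iter_ = len(trace)
        self.converged_ = True
        eta = self._eta(Zs)
        pi_rows = np.exp(eta - logsumexp(eta, axis=1)[:, None])
        self.class_weights_ = (counts[:, None] * pi_rows).sum(axis=0) / counts.sum()
        self._finalize()
        if np.any(np.abs(coefs[:, 1:]) > 15.0):
            warnings.warn(
                "separation in the structural multinomial model", ConvergenceWarning
            )
        return self

    def _eta(self, Z):
        design = np.column_stack([np.ones(len(Z)), Z])
        eta = design @ self._struct_coefs_.T
        return np.column_stack([eta, np.zeros(len(Z))])

    def _run_conditional_em(self, patterns, Zs, counts, resp, n_iter, coefs=None,
                            trace=None, n_newton=3):
        k, nz = self.n_classes, Zs.shape[1]
        if coefs is None:
            coefs = np.zeros((k - 1, 1 + nz))
        trace = list(trace) if trace else []
        ll_old = -np.inf
        design = np.column_stack([np.ones(len(Zs)), Zs])
        for _ in range(n_iter):
            _, probs = self._m_step_measurement(patterns, counts, resp)
            self.item_probs_ = probs
            coefs = self._m_step_structural(design, counts, resp, coefs, n_newton)
            self._struct_coefs_ = coefs
            eta = self._eta(Zs)
            log_pi = eta - logsumexp(eta, axis=1)[:, None]
            L = _pattern_loglik(patterns, probs) + log_pi
            norm = logsumexp(L, axis=1)
            resp = np.exp(L - norm[:, None])
            ll = float(counts @ norm)
            trace.append(ll)
            if ll - ll_old < self.tol * (abs(ll_old) + 1.0) and len(trace) > 1:
                break
            ll_old = ll
        return ll, resp, coefs, self.item_probs_, trace

    def _m_step_structural(self, design, counts, resp, coefs0, n_newton: int = 3):
        # damped Newton on the expected multinomial-logit log-likelihood;
        # a partial M-step suffices (generalized EM)
        k = self.n_classes
        target = counts[:, None] * resp  # expected class counts per pattern
        B = coefs0.copy()
        d = design.shape[1]

        def ll(B):
            eta = np.column_stack([design @ B.T, np.zeros(len(design))])
            return float(np.sum(target * eta) - counts @ logsumexp(eta, axis=1))

        f0 = ll(B)
        for _ in range(n_newton):
            eta = np.column_stack([design @ B.T, np.zeros(len(design))])
            pi = np.exp(eta - logsumexp(eta, axis=1)[:, None])
            P = pi[:, :-1]
            G = (target[:, :-1] - counts[:, None] * P).T @ design  # (k-1, d)
            cP = counts[:, None] * P
            H = np.zeros((k - 1, d, k - 1, d))
            for x in range(k - 1):
                H[x, :, x, :] = design.T @ (cP[:, x : x + 1] * design)
            H -= np.einsum("s,sx,sa,sy,sb->xayb", counts, P, design, P, design)
            Hm = H.reshape((k - 1) * d, (k - 1) * d)
            Hm[np.diag_indices_from(Hm)] += 1e-10
            try:
                step = np.linalg.solve(Hm, G.ravel()).reshape(k - 1, d)
            except np.linalg.LinAlgError:
                break
            for _ in range(20):
                f1 = ll(B + step)
                if f1 >= f0 - 1e-12:
                    break
                step = step / 2.0
            if f1 < f0 - 1e-12:
                break
            B, f0 = B + step, f1
        return B

    @property
    def structural_coefs_(self) -> np.ndarray:
        """(k-1, 1+c) multinomial-logit coefficients (intercept, slopes)."""
        return self._struct_coefs_

    def reorder(self, perm):
        perm = np.asarray(perm)
        # re-express structural coefficients with the new reference (last) class
        full = np.vstack([self._struct_coefs_, np.zeros((1, self._struct_coefs_.shape[1]))])
        full = full[perm]
        self._struct_coefs_ = full[:-1] - full[-1]
        return super().reorder(perm)

    def predict_proba(self, U, Z) -> np.ndarray:
        """Posterior P(X=x | U, z), conditioning on the covariates."""
        enc = encode_indicators(U)
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[0] != enc.shape[0]:
            Z = Z.T
        eta = self._eta(Z)
        log_pi = eta - logsumexp(eta, axis=1)[:, None]
        L = _pattern_loglik(enc, self.item_probs_) + log_pi
        return np.exp(L - logsumexp(L, axis=1)[:, None])
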