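"""Updated pseudo class draws (uPCD).

uPCD imputes latent class membership from posteriors that condition on
the mediator and outcome, P(X | U, M, Y), without ever fitting a
conditional class-derivation model.  Starting from an unconditional
latent class fit, the structural parameters (alpha, beta) and the class
posteriors are updated in an alternating chain:

0. fit the unconditional LCA; save (gamma, tau) and their joint
   sampling covariance;
1. fit null structural models (Y on M only; M on intercept only) and
   perturb their coefficients from the fitted covariances;
2. perturb (gamma, tau) from the step-0 covariance and combine with the
   current (alpha, beta) to form P(X=x | U, M, Y) for every person;
3. draw a class W per person from that posterior, refit both logistic
   models on (W, M, Y), and perturb the new (alpha, beta);
4. repeat 2-3; perturbation means the chain converges to a stable
   distribution rather than a point;
5. after a burn-in, store the current W every ``thin`` iterations until
   ``n_draws`` imputations exist, then fit the mediation model per
   imputation and pool with Rubin's rules.

The Gaussian perturbation propagates class-derivation uncertainty into
the pooled standard errors -- the feature that distinguishes uPCD (and
the one-step model) from the other linking methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import kendalltau

from .lca import BinaryLCA, ConvergenceWarning, _compress, _pattern_loglik, encode_indicators
from .linking import EmptyClassError, _LinkingBase, _multinomial_draw, _pool_effects
from .mediation import (
    MediationEffects,
    aggregate_cells,
    fit_mediator_model,
    fit_outcome_model,
    fit_structural,
    fit_structural_fast,
    mediation_effects,
    mediator_design,
    outcome_design,
)

__all__ = [
    "UpcdConfig",
    "UpdatedPCDMediation",
    "perturb_params",
    "upcd_posterior",
    "diagnose_trace",
    "mann_kendall",
    "run_upcd",
]


@dataclass
class UpcdConfig:
    """Chain schedule and switches for uPCD."""

    burn_in: int = 100
    thin: int = 20
    m: int = 80
    seed: int | None = None
    perturb: bool = True
    firth_on_separation: bool = True
    independent_restarts: bool = False  # re-run burn-in before every stored draw

    def __post_init__(self):
        if min(self.burn_in, self.thin, self.m) < 1:
            raise ValueError("burn_in, thin and m must be positive")


def perturb_params(estimate: np.ndarray, cov: np.ndarray, rng) -> np.ndarray:
    """Gaussian perturbation: estimate + N(0, cov) draw.

    The covariance is repaired to PSD by flooring negative eigenvalues at
    zero before the Cholesky-style draw; a zero covariance returns the
    estimate unchanged.
    """
    estimate = np.asarray(estimate, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if not np.any(cov):
        return estimate.copy()
    eigval, eigvec = np.linalg.eigh((cov + cov.T) / 2.0)
    root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    return estimate + root @ rng.standard_normal(len(estimate))


def upcd_posterior(
    gamma: np.ndarray,
    tau: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    U,
    M,
    Y,
    C=None,
) -> np.ndarray:
    """Class posteriors P(X=x | U, M, Y) under the supplied parameters.

    probs[i, x] is proportional to
    pi_x * prod_j P(U_ij | tau_xj) * P(M_i | x; alpha) * P(Y_i | x, M_i; beta),
    row-normalized on the log scale.  With all structural slopes at zero
    the mediator/outcome factors cancel and this reduces to the
    unconditional posterior.
    """
    enc = U if (isinstance(U, np.ndarray) and U.dtype == np.int8) else encode_indicators(U)
    k = tau.shape[0]
    g = np.concatenate([np.asarray(gamma, dtype=float), [0.0]])
    log_pi = g - logsumexp(g)
    probs = expit(np.asarray(tau, dtype=float))
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = len(M)
    classes = np.arange(k)
    Wx = np.repeat(classes[None, :], n, axis=0).ravel()
    Cx = None if C is None else np.repeat(np.asarray(C, dtype=float).reshape(n, -1), k, axis=0)
    Mx = np.repeat(M, k)
    pm = expit(mediator_design(Wx, k, Cx) @ alpha).reshape(n, k)
    py = expit(outcome_design(Wx, Mx, k, Cx) @ beta).reshape(n, k)
    L = _pattern_loglik(enc, np.clip(probs, 1e-12, 1 - 1e-12)) + log_pi
    L = L + np.where(M[:, None] == 1, np.log(pm), np.log1p(-pm))
    L = L + np.where(Y[:, None] == 1, np.log(py), np.log1p(-py))
    return np.exp(L - logsumexp(L, axis=1)[:, None])


def mann_kendall(x: np.ndarray) -> tuple[float, float]:
    """Mann-Kendall trend statistic via Kendall's tau against time.

    Returns (tau, p-value); small p indicates a monotone trend in the
    trace, i.e. the chain has not reached its stable distribution.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 8:
        return 0.0, 1.0
    tau, p = kendalltau(np.arange(len(x)), x)
    return float(tau), float(p)


@dataclass
class UpcdState:
    """Mutable chain state with a per-iteration trace."""

    iteration: int
    alpha: np.ndarray
    beta: np.ndarray
    gamma_tau: np.ndarray
    current_W: np.ndarray
    alpha_trace: list = field(default_factory=list)
    beta_trace: list = field(default_factory=list)
    class_size_trace: list = field(default_factory=list)
    cell_trace: list = field(default_factory=list)
    empty_class_events: int = 0
    separation_events: int = 0


def diagnose_trace(
    state: UpcdState,
    max_threshold_se: float | None = None,
    cohort_max_threshold_ses=None,
    alpha_level: float = 0.01,
) -> dict:
    """Convergence report for a uPCD chain.

    Checks (a) the within-class threshold-SE exclusion rule against the
    cohort of replicate maxima (excluded when this dataset's maximum
    exceeds strictly twice the cohort average of the maxima), (b) empty
    cells in the W x M x Y cross-tabs, and (c) stationarity of the
    structural-parameter traces by Mann-Kendall.
    """
    report: dict = {}
    if max_threshold_se is not None and cohort_max_threshold_ses is not None:
        avg = float(np.mean(cohort_max_threshold_ses))
        report["threshold_se_rule"] = {
            "max_se": max_threshold_se,
            "cohort_avg_max_se": avg,
            "excluded": bool(max_threshold_se > 2.0 * avg),
        }
    else:
        report["threshold_se_rule"] = {
            "max_se": max_threshold_se,
            "excluded": None,
            "note": "not evaluable without a cohort of replicates",
        }
    cells = np.asarray(state.cell_trace)
    report["empty_cell_iterations"] = int(np.sum(np.any(cells == 0, axis=1))) if len(cells) else 0
    report["empty_class_events"] = state.empty_class_events
    report["separation_events"] = state.separation_events

    at = np.asarray(state.alpha_trace)
    bt = np.asarray(state.beta_trace)
    pvals = []
    if len(at):
        sl = slice(len(at) // 2, None, max(1, len(at) // 400))
        for series in np.column_stack([at, bt]).T:
            pvals.append(mann_kendall(series[sl])[1])
    n_tests = max(1, len(pvals))
    report["trace_trend_pvalues"] = pvals
    report["stationary"] = bool(all(p > alpha_level / n_tests for p in pvals)) if pvals else None
    report["pass"] = bool(
        report["threshold_se_rule"].get("excluded") is not True
        and (report["stationary"] is not False)
    )
    return report


def trace_frame(state: UpcdState) -> pd.DataFrame:
    """Plot-ready trace table: structural parameters and cell counts."""
    at = np.asarray(state.alpha_trace)
    bt = np.asarray(state.beta_trace)
    cols = {f"alpha{j}": at[:, j] for j in range(at.shape[1])}
    cols.update({f"beta{j}": bt[:, j] for j in range(bt.shape[1])})
    sizes = np.asarray(state.class_size_trace)
    cols.update({f"n_class{x + 1}": sizes[:, x] for x in range(sizes.shape[1])})
    return pd.DataFrame(cols)


class UpdatedPCDMediation(_LinkingBase):
    """The uPCD estimator (see module docstring for the algorithm).

    Parameters beyond the shared linking options:

    burn_in : iterations before the first stored imputation (default 100).
    thin : iterations between stored imputations (default 20).
    n_draws : number of stored imputations m (default 80).
    perturb : Gaussian perturbation of all parameters each cycle; turning
        it off collapses uPCD onto a conditional variant of nPCD and
        understates the pooled SE.
    """

    _method = "upcd"

    def __init__(
        self,
        n_classes: int = 4,
        burn_in: int = 100,
        thin: int = 20,
        n_draws: int = 80,
        perturb: bool = True,
        independent_restarts: bool = False,
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
        self.burn_in = burn_in
        self.thin = thin
        self.n_draws = n_draws
        self.perturb = perturb
        self.independent_restarts = independent_restarts

    # one chain cycle: perturb LCA params -> posterior -> draw W -> refit
    def _iterate(self, state: UpcdState, data, rng) -> UpcdState:
        enc_patterns, inverse, Ms, Ys, Cs, M, Y, C, theta_hat, cov_lca = data
        k = self.n_classes
        for attempt in range(2):
            gt = (
                theta_hat + cov_lca @ rng.standard_normal(len(theta_hat))
                if self.perturb
                else theta_hat.copy()
            )
            gamma, tau = gt[: k - 1], gt[k - 1 :].reshape(k, -1)
            post = upcd_posterior(gamma, tau, state.alpha, state.beta,
                                  enc_patterns, Ms, Ys, Cs)
            # patterns share posteriors only through U; M/Y enter per pattern
            W = _multinomial_draw(post[inverse], rng)
            sizes = np.bincount(W, minlength=k)
            if np.all(sizes > 0):
                break
            state.empty_class_events += 1
        else:
            raise EmptyClassError(
                "imputed latent class with a prevalence of zero in consecutive draws"
            )
        if C is None:
            Wc, Mc, Yc, wts = aggregate_cells(W, M, Y, k)
            fm = fit_mediator_model(Wc, Mc, k, None, wts,
                                    firth_on_separation=self.firth_on_separation)
            fy = fit_outcome_model(Wc, Mc, Yc, k, None, wts,
                                   firth_on_separation=self.firth_on_separation)
        else:
            fm = fit_mediator_model(W, M, k, C, firth_on_separation=self.firth_on_separation)
            fy = fit_outcome_model(W, M, Y, k, C, firth_on_separation=self.firth_on_separation)
        if fm.separation or fy.separation:
            state.separation_events += 1
        alpha = perturb_params(fm.coef, fm.cov, rng) if self.perturb else fm.coef
        beta = perturb_params(fy.coef, fy.cov, rng) if self.perturb else fy.coef
        state.alpha, state.beta, state.gamma_tau = alpha, beta, gt
        state.current_W = W
        state.iteration += 1
        state.alpha_trace.append(fm.coef.copy())
        state.beta_trace.append(fy.coef.copy())
        state.class_size_trace.append(sizes)
        cells = np.bincount(W * 4 + M * 2 + Y, minlength=4 * k)
        state.cell_trace.append(cells)
        return state

    def fit(self, U, M, Y, C=None, lca: BinaryLCA | None = None,
            cohort_max_threshold_ses=None):
        M = np.asarray(M, dtype=np.int64)
        Y = np.asarray(Y, dtype=np.int64)
        n = len(M)
        C = self._conf(C, n)
        k = self.n_classes
        ss = self._seed_seq()
        lca_seed = ss.generate_state(1)[0]
        rng = np.random.default_rng(ss.spawn(1)[0])

        # Step 0: unconditional LCA with joint (gamma, tau) covariance
        self.lca_ = lca if lca is not None else self._fit_lca(U, lca_seed)
        if self.lca_.covariance_ is None:
            self.lca_.estimate_covariance()
        cov = self.lca_.covariance_
        theta_hat = self.lca_._theta()
        # pre-factor the (gamma, tau) covariance for fast per-iteration draws
        eigval, eigvec = np.linalg.eigh((cov.cov + cov.cov.T) / 2.0)
        cov_lca = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
        self.max_threshold_se_ = cov.max_threshold_se

        # compress U patterns once; posteriors depend on (pattern, M, Y)
        enc = encode_indicators(U)
        upat, uinv, _ = _compress(enc)
        joint = np.column_stack([uinv, M, Y] if C is None else [uinv, M, Y, *C.T])
        _, first, jinv = np.unique(
            joint, axis=0, return_index=True, return_inverse=True
        )
        jinv = jinv.ravel()
        patterns = enc[first]
        Ms, Ys = M[first], Y[first]
        Cs = None if C is None else C[first]
        data = (patterns, jinv, Ms, Ys, Cs, M, Y, C, theta_hat, cov_lca)

        # Step 1: null structural fits, perturbed
        Xa0 = np.ones((n, 1))
        Xb0 = np.column_stack([np.ones(n), M.astype(float)])
        from .glm import fit_logistic

        fa = fit_logistic(Xa0, M.astype(float))
        fb = fit_logistic(Xb0, Y.astype(float))
        nc = 0 if C is None else C.shape[1]
        alpha = np.zeros(k + nc)
        beta = np.zeros(2 * k + nc)
        a0 = perturb_params(fa.coef, fa.cov, rng) if self.perturb else fa.coef
        b0 = perturb_params(fb.coef, fb.cov, rng) if self.perturb else fb.coef
        alpha[0] = a0[0]
        beta[:2] = b0
        state = UpcdState(0, alpha, beta, theta_hat.copy(), np.zeros(n, dtype=int))

        draws = []
        draw_iters = []
        if self.independent_restarts:
            while len(draws) < self.n_draws:
                for _ in range(self.burn_in):
                    state = self._iterate(state, data, rng)
                draws.append(state.current_W.copy())
                draw_iters.append(state.iteration)
        else:
            for _ in range(self.burn_in):
                state = self._iterate(state, data, rng)
            while len(draws) < self.n_draws:
                for _ in range(self.thin):
                    state = self._iterate(state, data, rng)
                draws.append(state.current_W.copy())
                draw_iters.append(state.iteration)
        self.draw_iterations_ = np.asarray(draw_iters)
        self.state_ = state
        self.trace_ = trace_frame(state)

        per_draw = []
        for W in draws:
            if C is None:
                sp = fit_structural_fast(W, M, Y, k, self.firth_on_separation)
            else:
                sp = fit_structural(W, M, Y, k, C,
                                    firth_on_separation=self.firth_on_separation)
            eff = mediation_effects(sp, C_rows=C, class_names=self._names())
            per_draw.append(eff)
        self.draws_ = np.column_stack(draws)
        self.effects_ = _pool_effects(per_draw, self._names())
        self.effects_.method = self._method
        self.diagnostics_ = diagnose_trace(
            state, self.max_threshold_se_, cohort_max_threshold_ses
        )
        self.effects_.diagnostics.update(self.diagnostics_)
        if self.diagnostics_["threshold_se_rule"].get("excluded"):
            warnings.warn(
                "dataset flagged by the threshold-SE exclusion rule",
                ConvergenceWarning,
            )
        return self


def run_upcd(
    U, M, Y, C=None, k=4, burn_in=100, thin=20, m=80, seed=None,
    config: UpcdConfig | None = None, **kw,
) -> MediationEffects:
    """Functional wrapper; a ``UpcdConfig`` overrides the schedule arguments."""
    if config is not None:
        burn_in, thin, m, seed = config.burn_in, config.thin, config.m, config.seed
        kw.setdefault("perturb", config.perturb)
        kw.setdefault("firth_on_separation", config.firth_on_separation)
        kw.setdefault("independent_restarts", config.independent_restarts)
    est = UpdatedPCDMediation(
        n_classes=k, burn_in=burn_in, thin=thin, n_draws=m, random_state=seed, **kw
    ).fit(U, M, Y, C)
    return est.effects_
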