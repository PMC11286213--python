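"""Synthetic data for the latent-class mediation simulation study.

The generator emulates a developmental-cohort setting: a four-class
trajectory exposure (Early-Onset Persistent 8%, Adolescent Onset 10%,
Childhood Limited 12%, Low 70%) measured by five binary indicators, a
binary mediator (P(M=1) = 0.20 marginally) and a binary outcome
(P(Y=1) = 0.378 marginally), with an exposure-mediator interaction.  The
mediator and outcome conditionals are fixed by a 4 x 2 x 2 population
cross-tabulation (counts per 5,000), from which the true counterfactual
effects follow in closed form.

The three study conditions differ only in the separation of the
measurement model: item-response profiles are calibrated by scaling the
class profiles around their per-item logit midpoints until the exact
population relative entropy hits 0.90 (good), 0.80 (medium) or 0.70
(poor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit, logsumexp

from .lca import _pattern_loglik
from .mediation import MediationEffects, StructuralParams, mediation_effects

__all__ = [
    "SimScenario",
    "SimDataset",
    "CLASS_NAMES",
    "CLASS_PROPS",
    "P_M_GIVEN_X",
    "P_Y_GIVEN_XM",
    "BASE_PROFILES",
    "scenario",
    "generate_dataset",
    "true_effects",
    "structural_params_from_probs",
    "calibrate_profiles",
    "population_entropy",
    "ENTROPY_TARGETS",
]

CLASS_NAMES = ["EOP", "AO", "CL", "Low"]
CLASS_PROPS = np.array([0.08, 0.10, 0.12, 0.70])

# Mediator and outcome conditionals implied by the population
# cross-tabulation (counts out of 5,000): P(M=1|X) and P(Y=1|X,M).
P_M_GIVEN_X = np.array([130 / 400, 175 / 500, 125 / 600, 570 / 3500])
P_Y_GIVEN_XM = np.array(
    [
        [120 / 270, 80 / 130],  # EOP: M=0, M=1
        [125 / 325, 100 / 175],  # AO
        [180 / 475, 60 / 125],  # CL
        [980 / 2930, 245 / 570],  # Low
    ]
)

# Canonical trajectory shapes for the five binary indicators: persistently
# high (EOP), increasing (AO), decreasing (CL), and uniformly low (Low).
BASE_PROFILES = np.array(
    [
        [0.8, 0.8, 0.8, 0.8, 0.8],  # EOP
        [0.1, 0.2, 0.4, 0.6, 0.8],  # AO
        [0.8, 0.6, 0.4, 0.2, 0.1],  # CL
        [0.1, 0.1, 0.1, 0.1, 0.1],  # Low
    ]
)

ENTROPY_TARGETS = {"good": 0.90, "medium": 0.80, "poor": 0.70}


@dataclass
class SimScenario:
    """A data-generating mechanism for the simulation study."""

    class_props: np.ndarray = field(default_factory=lambda: CLASS_PROPS.copy())
    item_profiles: np.ndarray = field(default_factory=lambda: BASE_PROFILES.copy())
    entropy_label: str = ""
    p_m_given_x: np.ndarray = field(default_factory=lambda: P_M_GIVEN_X.copy())
    p_y_given_x_m: np.ndarray = field(default_factory=lambda: P_Y_GIVEN_XM.copy())
    n_obs: int = 5000
    class_names: list[str] = field(default_factory=lambda: list(CLASS_NAMES))

    def __post_init__(self):
        self.class_props = np.asarray(self.class_props, dtype=float)
        self.item_profiles = np.asarray(self.item_profiles, dtype=float)
        self.p_m_given_x = np.asarray(self.p_m_given_x, dtype=float)
        self.p_y_given_x_m = np.asarray(self.p_y_given_x_m, dtype=float)
        if abs(self.class_props.sum() - 1.0) > 1e-10:
            raise ValueError("class proportions must sum to 1")
        for arr in (self.p_m_given_x, self.p_y_given_x_m):
            if np.any((arr <= 0) | (arr >= 1)):
                raise ValueError("conditional probabilities must lie in (0, 1)")

    @property
    def k(self) -> int:
        return len(self.class_props)

    def marginal_m(self) -> float:
        return float(self.class_props @ self.p_m_given_x)

    def marginal_y(self) -> float:
        p_y_x = (
            self.p_y_given_x_m[:, 0] * (1 - self.p_m_given_x)
            + self.p_y_given_x_m[:, 1] * self.p_m_given_x
        )
        return float(self.class_props @ p_y_x)


@dataclass
class SimDataset:
    """One simulated dataset with its generating truth attached."""

    true_class: np.ndarray
    U: pd.DataFrame
    M: np.ndarray
    Y: np.ndarray
    scenario: SimScenario
    seed: int | None = None

    @property
    def frame(self) -> pd.DataFrame:
        out = self.U.copy()
        out.insert(0, "true_class", self.true_class)
        out["m"] = self.M
        out["y"] = self.Y
        return out


def generate_dataset(s: SimScenario, seed=None) -> SimDataset:
    """Draw one dataset: X ~ cat(pi), U_j|X, M|X, Y|X,M all Bernoulli.

    Each variable uses an independent child stream of the seed, so e.g.
    enlarging the indicator block does not perturb the mediator draws.
    """
    ss = np.random.SeedSequence(seed)
    rx, ru, rm, ry = [np.random.default_rng(c) for c in ss.spawn(4)]
    n, k = s.n_obs, s.k
    X = rx.choice(k, size=n, p=s.class_props)
    U = (ru.random((n, s.item_profiles.shape[1])) < s.item_profiles[X]).astype(np.int8)
    M = (rm.random(n) < s.p_m_given_x[X]).astype(np.int8)
    Y = (ry.random(n) < s.p_y_given_x_m[X, M]).astype(np.int8)
    cols = [f"u{j + 1}" for j in range(U.shape[1])]
    return SimDataset(X, pd.DataFrame(U, columns=cols), M, Y, s, seed)


def structural_params_from_probs(
    p_m_given_x: np.ndarray, p_y_given_x_m: np.ndarray
) -> StructuralParams:
    """Saturated (alpha, beta) reproducing the given conditionals exactly."""
    k = len(p_m_given_x)
    la = logit(np.asarray(p_m_given_x, dtype=float))
    alpha = np.concatenate([[la[-1]], la[:-1] - la[-1]])
    ly = logit(np.asarray(p_y_given_x_m, dtype=float))  # (k, 2)
    b0 = ly[-1, 0]
    b1 = ly[-1, 1] - ly[-1, 0]
    bx = ly[:-1, 0] - b0
    bxm = (ly[:-1, 1] - ly[:-1, 0]) - b1
    beta = np.concatenate([[b0, b1], bx, bxm])
    na, nb = k, 2 * k
    return StructuralParams(
        alpha, beta, np.zeros((na, na)), np.zeros((nb, nb)), k, 0, "closed_form"
    )


def true_effects(s: SimScenario) -> MediationEffects:
    """Closed-form mediation effects implied by the scenario conditionals.

    No sampling is involved: the mediation formula is evaluated directly
    on P(M|X) and P(Y|X,M).  This is the truth theta used by the
    performance harness.
    """
    sp = structural_params_from_probs(s.p_m_given_x, s.p_y_given_x_m)
    eff = mediation_effects(sp, class_names=s.class_names, se=False)
    eff.method = "truth"
    return eff


# ---------------------------------------------------------------------------
# entropy calibration
# ---------------------------------------------------------------------------


def _all_patterns(p: int) -> np.ndarray:
    return np.array(
        [[(i >> j) & 1 for j in range(p)] for i in range(2**p)], dtype=np.int8
    )


def population_entropy(class_props: np.ndarray, item_profiles: np.ndarray) -> float:
    """Exact population relative entropy of the true-model posteriors.

    Enumerates all 2^p indicator patterns, weights each pattern's
    posterior entropy by its marginal probability.  Deterministic, so the
    calibration below needs no probe sample.
    """
    patterns = _all_patterns(item_profiles.shape[1])
    L = _pattern_loglik(patterns, np.clip(item_profiles, 1e-12, 1 - 1e-12)) + np.log(
        class_props
    )
    norm = logsumexp(L, axis=1)
    post = np.exp(L - norm[:, None])
    w = np.exp(norm)  # pattern marginal probabilities
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(post > 0, post * np.log(post), 0.0)
    k = len(class_props)
    return float(1.0 + (w @ plogp.sum(axis=1)) / np.log(k))


def _scaled_profiles(base: np.ndarray, scale: float) -> np.ndarray:
    """Scale class separation around per-item logit midpoints."""
    lg = logit(np.clip(base, 1e-9, 1 - 1e-9))
    mid = lg.mean(axis=0, keepdims=True)
    return expit(mid + scale * (lg - mid))


def calibrate_profiles(
    class_props: np.ndarray,
    base_profiles: np.ndarray,
    entropy_target: float,
    tol: float = 1e-3,
    bracket: tuple[float, float] = (0.05, 12.0),
    max_iter: int = 80,
) -> np.ndarray:
    """Item profiles whose population relative entropy hits the target.

    A single separation scalar applied on the logit scale around each
    item's midpoint is found by bisection; entropy is monotone increasing
    in the scalar over the bracket.
    """
    lo, hi = bracket

    def f(s):
        return population_entropy(class_props, _scaled_profiles(base_profiles, s))

    flo, fhi = f(lo), f(hi)
    if not (flo < entropy_target < fhi):
        raise ValueError(
            f"entropy target {entropy_target} outside achievable bracket "
            f"[{flo:.4f}, {fhi:.4f}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm - entropy_target) < tol:
            break
        if fm < entropy_target:
            lo = mid
        else:
            hi = mid
    return _scaled_profiles(base_profiles, mid)


_PRESET_CACHE: dict[str, np.ndarray] = {}


def scenario(entropy_label: str, n_obs: int = 5000) -> SimScenario:
    """Preset scenario with profiles calibrated to the named entropy level."""
    if entropy_label not in ENTROPY_TARGETS:
        raise ValueError(f"unknown entropy label {entropy_label!r}")
    if entropy_label not in _PRESET_CACHE:
        _PRESET_CACHE[entropy_label] = calibrate_profiles(
            CLASS_PROPS, BASE_PROFILES, ENTROPY_TARGETS[entropy_label], tol=1e-4
        )
    return SimScenario(
        item_profiles=_PRESET_CACHE[entropy_label].copy(),
        entropy_label=entropy_label,
        n_obs=n_obs,
    )
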