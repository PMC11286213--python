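"""Monte Carlo performance harness for the linking estimators.

Runs the six methods over independently seeded replicate datasets from a
scenario, applies the non-convergence exclusion rule, and computes the
standard simulation performance measures (bias, percentage bias,
coverage, bias-eliminated coverage, empirical SE, average model SE) with
their Monte Carlo standard errors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .lca import BinaryLCA
from .linking import (
    BCHMediation,
    InclusivePCD,
    ModalAssignmentMediation,
    NonInclusivePCD,
    OneStepMediation,
)
from .mediation import ESTIMANDS, MediationEffects
from .simulate import SimScenario, generate_dataset, true_effects
from .upcd import UpdatedPCDMediation

__all__ = [
    "ALL_METHODS",
    "run_replicates",
    "apply_exclusions",
    "performance",
    "run_study",
]

ALL_METHODS = ("onestep", "bch", "modal", "npcd", "incpcd", "upcd")

_SHARED_LCA_METHODS = {"bch", "modal", "npcd", "upcd"}


def _make_estimator(method: str, scenario: SimScenario, seed: int, draws: dict):
    common = dict(
        n_classes=scenario.k,
        reference_profiles=scenario.item_profiles,
        class_names=scenario.class_names,
        random_state=seed,
    )
    if method == "modal":
        return ModalAssignmentMediation(**common)
    if method == "bch":
        return BCHMediation(**common)
    if method == "npcd":
        return NonInclusivePCD(n_draws=draws.get("npcd", 40), **common)
    if method == "incpcd":
        return InclusivePCD(n_draws=draws.get("incpcd", 40), **common)
    if method == "onestep":
        return OneStepMediation(**common)
    if method == "upcd":
        return UpdatedPCDMediation(
            n_draws=draws.get("upcd", 80),
            burn_in=draws.get("burn_in", 100),
            thin=draws.get("thin", 20),
            **common,
        )
    raise ValueError(f"unknown method {method!r}")


def run_replicates(
    scenario: SimScenario,
    n_sim: int,
    methods=ALL_METHODS,
    seed: int | None = None,
    draws: dict | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Estimates table: one row per (replicate, method, comparison, estimand).

    Replicates are independently seeded from one root seed, so results do
    not depend on execution order.  A method failing on a replicate is
    recorded as excluded with its reason rather than aborting the run.
    The unconditional latent class fit (with its parameter covariance) is
    shared by the methods that start from it.
    """
    draws = draws or {}
    methods = list(methods)
    root = np.random.SeedSequence(seed)
    rep_seeds = root.spawn(n_sim)
    rows = []
    for r in range(n_sim):
        children = rep_seeds[r].spawn(1 + len(methods))
        data_seed = children[0].generate_state(1)[0]
        ds = generate_dataset(scenario, data_seed)
        shared_lca = None
        lca_max_se = np.nan
        onestep_max_se = np.nan
        lca_inflated = False
        onestep_inflated = False
        if any(m in _SHARED_LCA_METHODS for m in methods):
            try:
                shared_lca = BinaryLCA(
                    n_classes=scenario.k, random_state=int(data_seed) % (2**31)
                ).fit(ds.U)
                shared_lca.align(scenario.item_profiles)
                cov = shared_lca.estimate_covariance()
                lca_max_se = cov.max_threshold_se
                lca_inflated = cov.se_inflated
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                shared_lca = None
                warnings.warn(f"replicate {r}: unconditional LCA failed ({exc})")
        results = {}
        for j, method in enumerate(methods):
            mseed = int(children[1 + j].generate_state(1)[0]) % (2**31)
            est = _make_estimator(method, scenario, mseed, draws)
            failure = None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    if method in _SHARED_LCA_METHODS and shared_lca is not None:
                        est.fit(ds.U, ds.M, ds.Y, lca=shared_lca)
                    else:
                        est.fit(ds.U, ds.M, ds.Y)
                except Exception as exc:  # noqa: BLE001
                    failure = f"{type(exc).__name__}: {exc}"
            if method == "onestep" and failure is None:
                onestep_max_se = est.max_threshold_se_
                onestep_inflated = est.se_inflated_
            results[method] = (failure, None if failure else est.effects_)
        for method in methods:
            failure, eff = results[method]
            for i in range(scenario.k - 1):
                for jj, estimand in enumerate(ESTIMANDS):
                    rows.append(
                        {
                            "replicate": r,
                            "method": method,
                            "comparison": None if eff is None else eff.comparisons[i],
                            "estimand": estimand,
                            "estimate": np.nan if eff is None else eff.estimates[i, jj],
                            "model_se": np.nan if eff is None else eff.ses[i, jj],
                            "excluded": failure is not None,
                            "exclusion_reason": failure or "",
                            "lca_max_threshold_se": lca_max_se,
                            "onestep_max_threshold_se": onestep_max_se,
                            "lca_se_inflated": lca_inflated,
                            "onestep_se_inflated": onestep_inflated,
                        }
                    )
        if progress:
            print(f"replicate {r + 1}/{n_sim} done", flush=True)
    df = pd.DataFrame(rows)
    comp_map = {
        i: f"{scenario.class_names[i]} vs {scenario.class_names[-1]}"
        for i in range(scenario.k - 1)
    }
    # failed fits still get labelled comparisons for bookkeeping
    missing = df["comparison"].isna()
    if missing.any():
        idx = np.tile(
            np.repeat(np.arange(scenario.k - 1), len(ESTIMANDS)),
            missing.sum() // ((scenario.k - 1) * len(ESTIMANDS)),
        )
        df.loc[missing, "comparison"] = [comp_map[i] for i in idx]
    return df


def apply_exclusions(
    est: pd.DataFrame,
    lca_se_maxima: np.ndarray | None = None,
    onestep_se_maxima: np.ndarray | None = None,
    lca_inflated: np.ndarray | None = None,
    onestep_inflated: np.ndarray | None = None,
) -> pd.DataFrame:
    """Flag whole replicates by the threshold-SE non-convergence rule.

    A replicate is excluded for all methods when, in the unconditional
    latent class model or in the one-step model, either (a) the fit's
    inflated-SE flag fired (an SE beyond any plausible logit scale, or a
    near-zero information eigenvalue), or (b) its largest within-class
    threshold SE strictly exceeds twice the average of the per-replicate
    maxima across the non-flagged cohort.  Stage (a) keeps the stage-(b)
    average from being dominated by the very replicates the rule exists
    to remove.  Sources are logged separately in ``exclusion_reason``.
    """
    df = est.copy()
    per_rep = df.drop_duplicates("replicate").set_index("replicate")
    if lca_se_maxima is None:
        lca_se_maxima = per_rep["lca_max_threshold_se"].to_numpy()
    if onestep_se_maxima is None:
        onestep_se_maxima = per_rep["onestep_max_threshold_se"].to_numpy()
    if lca_inflated is None:
        lca_inflated = per_rep.get(
            "lca_se_inflated", pd.Series(False, index=per_rep.index)
        ).to_numpy()
    if onestep_inflated is None:
        onestep_inflated = per_rep.get(
            "onestep_se_inflated", pd.Series(False, index=per_rep.index)
        ).to_numpy()
    reasons = {}
    for name, maxima, flags in (
        (
            "unconditional_lca_threshold_se",
            np.asarray(lca_se_maxima, dtype=float),
            np.asarray(lca_inflated, dtype=bool),
        ),
        (
            "onestep_threshold_se",
            np.asarray(onestep_se_maxima, dtype=float),
            np.asarray(onestep_inflated, dtype=bool),
        ),
    ):
        valid = np.isfinite(maxima)
        if not valid.any():
            continue
        for rep, fl in zip(per_rep.index, flags):
            if fl:
                reasons.setdefault(rep, []).append(name + "_inflated")
        clean = valid & ~flags
        if clean.any():
            cutoff = 2.0 * np.mean(maxima[clean])
            for rep, mx, fl in zip(per_rep.index, maxima, flags):
                if not fl and np.isfinite(mx) and mx > cutoff:
                    reasons.setdefault(rep, []).append(name)
    for rep, why in reasons.items():
        mask = df["replicate"] == rep
        df.loc[mask, "excluded"] = True
        df.loc[mask, "exclusion_reason"] = (
            df.loc[mask, "exclusion_reason"].str.rstrip("; ")
            + ("; " if df.loc[mask, "exclusion_reason"].str.len().gt(0).any() else "")
            + "; ".join(why)
        )
    return df


def performance(est: pd.DataFrame, truth: MediationEffects) -> pd.DataFrame:
    """Morris-style performance table with Monte Carlo standard errors.

    Per (method, comparison, estimand) over non-excluded replicates:
    bias (and MCSE = emp_se/sqrt(n)), percentage bias, coverage of the
    nominal 95% Wald interval, bias-eliminated coverage (intervals judged
    against the mean estimate instead of the truth), empirical SE, and
    the average model SE.  Percentage bias is flagged unreliable when the
    true value is below 0.02 in magnitude.
    """
    truth_map = {}
    for i, comp in enumerate(truth.comparisons):
        for j, estimand in enumerate(ESTIMANDS):
            truth_map[(comp, estimand)] = truth.estimates[i, j]
    rows = []
    grouped = est[~est["excluded"]].groupby(["method", "comparison", "estimand"])
    for (method, comp, estimand), g in grouped:
        theta = truth_map[(comp, estimand)]
        th = g["estimate"].to_numpy(dtype=float)
        se = g["model_se"].to_numpy(dtype=float)
        ok = np.isfinite(th) & np.isfinite(se)
        th, se = th[ok], se[ok]
        n = len(th)
        if n < 2:
            continue
        mean = th.mean()
        bias = mean - theta
        emp_se = th.std(ddof=1)
        lo, hi = th - 1.96 * se, th + 1.96 * se
        cover = float(np.mean((lo <= theta) & (theta <= hi)))
        be_cover = float(np.mean((lo <= mean) & (mean <= hi)))
        rows.append(
            {
                "method": method,
                "comparison": comp,
                "estimand": estimand,
                "n_included": n,
                "truth": theta,
                "bias": bias,
                "bias_mcse": emp_se / np.sqrt(n),
                "pct_bias": 100.0 * bias / theta,
                "pct_bias_unreliable": bool(abs(theta) < 0.02),
                "coverage": cover,
                "coverage_mcse": np.sqrt(cover * (1 - cover) / n),
                "bias_elim_coverage": be_cover,
                "bias_elim_coverage_mcse": np.sqrt(be_cover * (1 - be_cover) / n),
                "emp_se": emp_se,
                "emp_se_mcse": emp_se / np.sqrt(2.0 * (n - 1)),
                "model_se_avg": se.mean(),
                "model_se_avg_mcse": se.std(ddof=1) / np.sqrt(n),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    return out.sort_values(["comparison", "estimand", "method"]).reset_index(drop=True)


def run_study(
    scenario: SimScenario,
    n_sim: int,
    methods=ALL_METHODS,
    seed: int | None = None,
    draws: dict | None = None,
    progress: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicates + exclusions + performance in one call."""
    est = run_replicates(scenario, n_sim, methods, seed, draws, progress)
    est = apply_exclusions(est)
    perf = performance(est, true_effects(scenario))
    return est, perf


def plot_bias(perf: pd.DataFrame, estimand: str, path=None):
    """Forest-style bias plot by method and comparison (one estimand)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = perf[perf["estimand"] == estimand]
    comps = sorted(sub["comparison"].unique())
    fig, axes = plt.subplots(1, len(comps), figsize=(4 * len(comps), 4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, comp in zip(axes, comps):
        rows = sub[sub["comparison"] == comp]
        y = np.arange(len(rows))
        ax.errorbar(rows["bias"], y, xerr=1.96 * rows["bias_mcse"], fmt="o")
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_yticks(y, rows["method"])
        ax.set_title(comp)
        ax.set_xlabel(f"bias in {estimand.upper()} (log RR)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
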