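"""Reading analysis datasets and writing fitted-model artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_dataset", "write_dataset", "lca_to_json", "write_posteriors"]


def read_dataset(
    path,
    indicator_prefix: str = "u",
    mediator_col: str = "m",
    outcome_col: str = "y",
    confounder_cols=(),
):
    """Load a delimited analysis dataset.

    Expects a header row; indicator columns start with
    ``indicator_prefix`` (empty cells or NA mean a missing indicator);
    the mediator and outcome must be complete binary columns.

    Returns (U, M, Y, C) with C ``None`` when no confounders requested.
    """
    df = pd.read_csv(path)
    u_cols = [c for c in df.columns if c.startswith(indicator_prefix) and c not in
              (mediator_col, outcome_col)]
    if not u_cols:
        raise ValueError(f"no indicator columns with prefix {indicator_prefix!r}")
    U = df[u_cols]
    M = df[mediator_col].to_numpy(dtype=np.int64)
    Y = df[outcome_col].to_numpy(dtype=np.int64)
    C = df[list(confounder_cols)].to_numpy(dtype=float) if confounder_cols else None
    return U, M, Y, C


def write_dataset(ds, path) -> None:
    """Write a simulated dataset as CSV (true_class, u1..up, m, y)."""
    ds.frame.to_csv(path, index=False)


def lca_to_json(lca, path=None) -> dict:
    """Serialize a fitted latent class model (parameters, SEs, flags)."""
    out = {
        "n_classes": int(lca.n_classes),
        "class_weights": lca.class_weights_.tolist(),
        "class_logits": lca.class_logits_.tolist(),
        "item_probs": lca.item_probs_.tolist(),
        "item_logits": lca.item_logits_.tolist(),
        "loglik": float(lca.loglik_),
        "n_params": int(lca.n_params_),
        "converged": bool(lca.converged_),
    }
    if getattr(lca, "covariance_", None) is not None:
        out["param_se"] = lca.covariance_.se.tolist()
        out["inflated_se_flags"] = lca.covariance_.inflated.tolist()
        out["max_threshold_se"] = lca.covariance_.max_threshold_se
    if path is not None:
        Path(path).write_text(json.dumps(out, indent=2))
    return out


def write_posteriors(post: np.ndarray, path) -> None:
    cols = [f"p_class{x + 1}" for x in range(post.shape[1])]
    pd.DataFrame(post, columns=cols).to_csv(path, index=False)
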