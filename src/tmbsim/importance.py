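"""Factor ranking over grid results: boosted-tree regressors explained by
exact tree-path-dependent Shapley values.

The bespoke parts are the feature encoding (recall/precision collapsed to
the single signed rgbrp scalar, which removes their collinearity) and the
collinearity screen; the regressor is standard gradient boosting with
squared-error (RMSE) loss.

Shapley attribution is computed exactly per tree by carrier-subset
enumeration: only the features a tree actually splits on carry non-zero
Shapley value, so for shallow trees the 2^|used| conditional expectations
(cover-weighted, i.e. tree-path-dependent) are enumerable and the classic
factorial-weighted Shapley sum is exact and deterministic.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor

from .records import ValidationError

__all__ = [
    "FEATURE_COLUMNS",
    "TARGET_COLUMNS",
    "assemble_features",
    "tree_shap_values",
    "rank_factors",
]

FEATURE_COLUMNS = [
    "exonic_size_mb",
    "genes_per_mb",
    "rgbrp",
    "synonymous",
    "nonsense",
    "nonstop",
    "splice_site",
    "tss",
    "hotspot_filter",
    "vaf_cutoff",
]
TARGET_COLUMNS = ["r_squared", "rmsle", "discrete_accuracy"]

_TARGET_SOURCE = {
    "r_squared": "test_r_squared",
    "rmsle": "test_rmsle",
    "discrete_accuracy": "test_discrete_accuracy",
}


def assemble_features(results: pd.DataFrame, collinearity_threshold: float = 0.9) -> pd.DataFrame:
    """One feature row per grid combination, with collinearity screening.

    Detection accuracy enters as the single ``rgbrp`` scalar; constant
    feature columns are dropped with a warning; feature pairs with
    |Pearson r| above the threshold trigger a warning naming the pair.
    """
    df = results.copy()
    if "degenerate" in df.columns:
        df = df[~df["degenerate"].astype(bool)]
    if "genes_per_mb" not in df.columns:
        df["genes_per_mb"] = df["n_genes"] / df["exonic_size_mb"]
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"results table lacks feature columns {missing}")
    out = df[FEATURE_COLUMNS].astype(float).reset_index(drop=True)
    for tgt, src in _TARGET_SOURCE.items():
        if src in df.columns:
            out[tgt] = df[src].to_numpy(dtype=float)
    targets_present = [t for t in TARGET_COLUMNS if t in out.columns]
    if not targets_present:
        raise ValidationError("results table carries no target metric columns")
    if out[targets_present].isna().any().any():
        raise ValidationError("missing target values; filter degenerate rows first")

    for col in list(out.columns):
        if col in FEATURE_COLUMNS and out[col].nunique() <= 1:
            warnings.warn(f"feature {col!r} is constant; dropped")
            out = out.drop(columns=[col])
    feats = [c for c in FEATURE_COLUMNS if c in out.columns]
    for a, b in combinations(feats, 2):
        r = np.corrcoef(out[a], out[b])[0, 1]
        if abs(r) > collinearity_threshold:
            warnings.warn(f"collinear features {a!r} and {b!r} (|r| = {abs(r):.3f})")
    return out


def _tree_arrays(tree):
    return (
        tree.children_left,
        tree.children_right,
        tree.feature,
        tree.threshold,
        tree.value[:, 0, 0],
        tree.weighted_n_node_samples,
    )


def _expvalue(node, in_subset, X, left, right, feat, thresh, value, weight):
    """Path-dependent conditional expectation of a tree for every row of X."""
    if left[node] == -1:
        return np.full(X.shape[0], value[node])
    f = feat[node]
    lv = _expvalue(left[node], in_subset, X, left, right, feat, thresh, value, weight)
    rv = _expvalue(right[node], in_subset, X, left, right, feat, thresh, value, weight)
    if in_subset[f]:
        return np.where(X[:, f] <= thresh[node], lv, rv)
    wl, wr = weight[left[node]], weight[right[node]]
    return (wl * lv + wr * rv) / (wl + wr)


def _single_tree_shap(tree, X: np.ndarray) -> np.ndarray:
    """Exact path-dependent Shapley values of one regression tree.

    Features the tree never splits on have Shapley value 0 (carrier
    property), so the subset lattice is enumerated over used features only.
    """
    left, right, feat, thresh, value, weight = _tree_arrays(tree)
    used = sorted({int(f) for f in feat if f >= 0})
    phi = np.zeros((X.shape[0], X.shape[1]))
    if not used:
        return phi
    u = len(used)
    n_features = X.shape[1]
    # v[mask] = E[f(x) | features in mask fixed at x]
    v = {}
    for mask in range(2**u):
        in_subset = np.zeros(n_features, dtype=bool)
        for j in range(u):
            if mask >> j & 1:
                in_subset[used[j]] = True
        v[mask] = _expvalue(0, in_subset, X, left, right, feat, thresh, value, weight)
    fact = [math.factorial(k) for k in range(u + 1)]
    for j, f in enumerate(used):
        bit = 1 << j
        for mask in range(2**u):
            if mask & bit:
                continue
            s = bin(mask).count("1")
            w = fact[s] * fact[u - s - 1] / fact[u]
            phi[:, f] += w * (v[mask | bit] - v[mask])
    return phi


def tree_shap_values(model: GradientBoostingRegressor, X: np.ndarray) -> np.ndarray:
    """Shapley values of a fitted gradient-boosting regressor on X.

    Exact and deterministic; satisfies the efficiency property
    ``base + phi.sum(axis=1) == model.predict(X)``.
    """
    X = np.asarray(X, dtype=float)
    phi = np.zeros_like(X, dtype=float)
    for stage in model.estimators_:
        phi += model.learning_rate * _single_tree_shap(stage[0].tree_, X)
    return phi


def rank_factors(
    rows: pd.DataFrame,
    target_name: str,
    seed: int = 0,
    n_estimators: int = 200,
    max_depth: int = 3,
    max_shap_rows: int = 500,
) -> pd.DataFrame:
    """Mean |Shapley| importance of each technical factor for one metric.

    Fits a gradient-boosting regressor (squared-error loss) of the target on
    the feature columns and ranks features by mean absolute Shapley value,
    descending.  Deterministic given the seed.
    """
    if len(rows) < 100:
        raise ValidationError(f"need >= 100 rows to rank factors, got {len(rows)}")
    if target_name not in rows.columns:
        raise ValidationError(f"unknown target {target_name!r}")
    feats = [c for c in FEATURE_COLUMNS if c in rows.columns]
    X = rows[feats].to_numpy(dtype=float)
    y = rows[target_name].to_numpy(dtype=float)
    model = GradientBoostingRegressor(
        loss="squared_error",
        n_estimators=n_estimators,
        max_depth=max_depth,
        learning_rate=0.1,
        random_state=seed,
    )
    model.fit(X, y)
    n_eval = min(max_shap_rows, len(X))
    idx = np.random.default_rng(seed).choice(len(X), size=n_eval, replace=False)
    phi = tree_shap_values(model, X[idx])
    imp = np.abs(phi).mean(axis=0)
    out = pd.DataFrame({"feature": feats, "mean_abs_shap": imp})
    return out.sort_values("mean_abs_shap", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
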