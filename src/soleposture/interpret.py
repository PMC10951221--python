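"""Model interpretation: common features, Shapley values, key features.

The Shapley value of feature j for one subject is its average marginal
contribution to the model output over all coalitions of the other
features, where a feature "absent" from a coalition is replaced by a
background sample (the interventional expectation over a background set):

    phi_j = sum_{T subset of S\\{j}}  |T|! (|S|-|T|-1)! / |S|!
            * ( v(T + {j}) - v(T) ),
    v(T)  = E_b [ f(x with features in T, background b elsewhere) ].

Small subsets are enumerated exactly (local accuracy then holds to
round-off); larger subsets use a seeded permutation-sampling estimator.
The model output explained is the positive-class probability when the
model exposes one, and the decision value otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .selection import CVReport, SelectionResult

#: A feature is "common" when selected by at least this many of the 5 models.
COMMON_MIN_MODELS = 3

#: Largest subset enumerated exactly; beyond this, permutation sampling.
MAX_EXACT_FEATURES = 16


def common_features(
    selection_results: list[SelectionResult], min_models: int = COMMON_MIN_MODELS
) -> list[str]:
    """Features appearing in >= min_models of the optimal subsets.

    Returned in descending count order, ties by first appearance.
    """
    counts: dict[str, int] = {}
    order: dict[str, int] = {}
    for res in selection_results:
        for name in set(res.optimal_subset):
            counts[name] = counts.get(name, 0) + 1
            order.setdefault(name, len(order))
    return sorted(
        (n for n, c in counts.items() if c >= min_models),
        key=lambda n: (-counts[n], order[n]),
    )


# ---------------------------------------------------------------------------
# Shapley values
# ---------------------------------------------------------------------------

@dataclass
class ShapleyResult:
    """Per-subject, per-feature Shapley values for one model."""

    values: pd.DataFrame  # rows: evaluation subjects, cols: features
    base_value: float  # expected model output over the background
    mean_abs: pd.Series  # mean |phi| per feature
    top_feature: str
    method: str  # "exact" | "sampling"


def _model_output(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        return proba[:, -1]
    return np.asarray(model.decision_function(X), dtype=float)


def _coalition_values(
    model, X_explain: np.ndarray, background: np.ndarray, p: int
) -> dict[frozenset, np.ndarray]:
    """v(T) for every coalition T: mean model output with features outside
    T replaced by each background row in turn."""
    n_e = len(X_explain)
    n_b = len(background)
    values: dict[frozenset, np.ndarray] = {}
    for size in range(p + 1):
        for T in combinations(range(p), size):
            Z = np.repeat(background[None, :, :], n_e, axis=0)  # (n_e, n_b, p)
            if T:
                Z[:, :, T] = X_explain[:, None, T]
            out = _model_output(model, Z.reshape(n_e * n_b, p))
            values[frozenset(T)] = out.reshape(n_e, n_b).mean(axis=1)
    return values


def _exact_shapley(
    model, X_explain: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, float]:
    p = X_explain.shape[1]
    v = _coalition_values(model, X_explain, background, p)
    phi = np.zeros((len(X_explain), p))
    fact = [factorial(i) for i in range(p + 1)]
    for j in range(p):
        others = [i for i in range(p) if i != j]
        for size in range(p):
            w = fact[size] * fact[p - size - 1] / fact[p]
            for T in combinations(others, size):
                Ts = frozenset(T)
                phi[:, j] += w * (v[Ts | {j}] - v[Ts])
    base = float(v[frozenset()].mean())
    return phi, base


def _sampled_shapley(
    model,
    X_explain: np.ndarray,
    background: np.ndarray,
    n_permutations: int,
    seed: int,
) -> tuple[np.ndarray, float]:
    rng = np.random.default_rng(seed)
    n_e, p = X_explain.shape
    n_b = len(background)
    phi = np.zeros((n_e, p))
    for _ in range(n_permutations):
        perm = rng.permutation(p)
        Z = np.repeat(background[None, :, :], n_e, axis=0)
        prev = _model_output(model, Z.reshape(n_e * n_b, p)).reshape(n_e, n_b).mean(1)
        for j in perm:
            Z[:, :, j] = X_explain[:, None, j]
            cur = (
                _model_output(model, Z.reshape(n_e * n_b, p))
                .reshape(n_e, n_b)
                .mean(1)
            )
            phi[:, j] += cur - prev
            prev = cur
    phi /= n_permutations
    base = float(_model_output(model, background).mean())
    return phi, base


def shapley_values(
    model,
    X_explain: pd.DataFrame,
    background: pd.DataFrame,
    n_permutations: int = 200,
    seed: int = 0,
    max_exact: int = MAX_EXACT_FEATURES,
) -> ShapleyResult:
    """Interventional Shapley values of ``model`` on ``X_explain``.

    ``background`` supplies the replacement distribution for absent
    features (typically the training rows of the fold whose model is being
    explained).  Up to ``max_exact`` features the coalition sum is
    enumerated exactly; beyond that, ``n_permutations`` seeded permutation
    passes estimate it.
    """
    if len(background) == 0:
        raise ParameterError("background set must be non-empty")
    features = list(X_explain.columns)
    Xe = X_explain.to_numpy(dtype=float)
    Xb = background[features].to_numpy(dtype=float)
    p = len(features)
    if p <= max_exact:
        phi, base = _exact_shapley(model, Xe, Xb)
        method = "exact"
    else:
        phi, base = _sampled_shapley(model, Xe, Xb, n_permutations, seed)
        method = "sampling"
    values = pd.DataFrame(phi, index=X_explain.index, columns=features)
    mean_abs = values.abs().mean()
    return ShapleyResult(
        values=values,
        base_value=base,
        mean_abs=mean_abs,
        top_feature=str(mean_abs.idxmax()),
        method=method,
    )


# ---------------------------------------------------------------------------
# Key features and misclassification
# ---------------------------------------------------------------------------

@dataclass
class KeyFeatureSet:
    """Common features, top Shapley features and their intersection."""

    common: dict[str, list[str]]  # task_set -> common feature names
    top_shapley: dict[str, list[str]]  # task_set -> each model's top feature
    key: list[str]  # unique names common AND top-Shapley in some task set
    zscores: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None


def key_features(
    common: dict[str, list[str]],
    top_shapley: dict[str, list[str]],
) -> KeyFeatureSet:
    """Intersect common and top-Shapley features per task set, deduplicated.

    A feature is *key* when, within some task-set analysis, it is both a
    common feature (>= 3 of 5 optimal subsets) and the top Shapley feature
    of at least one model.
    """
    key: list[str] = []
    for task_set, names in common.items():
        tops = set(top_shapley.get(task_set, []))
        for name in names:
            if name in tops and name not in key:
                key.append(name)
    return KeyFeatureSet(common=common, top_shapley=top_shapley, key=key)


def misclassified_subjects(
    reports: list[CVReport], min_models: int = COMMON_MIN_MODELS
) -> list[str]:
    """Subjects misclassified (out-of-fold) by >= min_models architectures."""
    counts: dict[str, int] = {}
    for rep in reports:
        wrong = rep.oof.loc[rep.oof["y_true"] != rep.oof["y_pred"], "subject_id"]
        for s in set(wrong):
            counts[s] = counts.get(s, 0) + 1
    return sorted(s for s, c in counts.items() if c >= min_models)


def group_zscores(
    X: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    features: list[str],
) -> pd.DataFrame:
    """Mean standardized value per group for each feature.

    Features are standardized against the pooled (all-subject) mean and SD
    so group z-scores are directly comparable; for two balanced groups the
    scores are opposite-signed.
    """
    labels = pd.Series(np.asarray(labels), index=X.index)
    sub = X[features]
    z = (sub - sub.mean()) / sub.std(ddof=1).replace(0.0, np.nan)
    out = z.groupby(labels).mean()
    out.index.name = "group"
    return out


def feature_correlation(X: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Pearson correlation matrix among the given features."""
    return X[features].corr(method="pearson")
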