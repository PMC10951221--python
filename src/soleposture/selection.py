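"""F pre-filter, forward sequential feature selection, tuning, CV reporting.

The selection stack mirrors the standard posturography-classifier recipe:

1. one-way ANOVA F pre-filter at alpha = 0.05 (a pruning step, not a
   significance claim);
2. greedy forward sequential feature selection (SFS) where each step adds
   the feature maximising the stratified 5-fold cross-validated F1 score
   of the architecture's default-hyperparameter model; the optimal subset
   is the path prefix with the highest CV F1;
3. grid-search hyperparameter tuning on the fixed optimal subset;
4. stratified 5-fold evaluation with per-fold accuracy/precision/recall/
   F1/Cohen's kappa, a vertically averaged ROC curve, AUC +/- SEM and the
   per-subject out-of-fold predictions kept for misclassification analysis.

Five architectures are supported: SVM, RF, LR, KNN and GNB.  The same
seeded fold partition is reused across architectures within an experiment
so that comparisons are paired.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    cohen_kappa_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from statsmodels.stats.anova import anova_lm

from .exceptions import ParameterError, StratificationError

ARCHITECTURES = ("SVM", "RF", "LR", "KNN", "GNB")

#: Bonferroni-corrected significance threshold for the three task-set
#: comparisons: 0.05 / 3 (printed as p < 0.017).
BONFERRONI_ALPHA = 0.05 / 3

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "SVM": {"C": [0.1, 1.0, 10.0], "kernel": ["linear", "rbf"]},
    "RF": {"n_estimators": [100, 300], "max_depth": [None, 5]},
    "LR": {"C": [0.1, 1.0, 10.0]},
    "KNN": {"n_neighbors": [3, 5, 7, 9], "weights": ["uniform", "distance"]},
    "GNB": {"var_smoothing": [1e-9, 1e-7]},
}


@dataclass
class ModelSpec:
    """One of the five classifier families plus its tuning grid and seed."""

    architecture: str
    grid: dict[str, list] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ParameterError(
                f"architecture must be one of {ARCHITECTURES}, got "
                f"{self.architecture!r}"
            )
        if not self.grid:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.architecture].items()}

    def build(self, **extra_params):
        """Instantiate the sklearn estimator with default + tuned params."""
        params = {**self.params, **extra_params}
        arch = self.architecture
        if arch == "SVM":
            return SVC(random_state=self.seed, **params)
        if arch == "RF":
            return RandomForestClassifier(random_state=self.seed, **params)
        if arch == "LR":
            return LogisticRegression(max_iter=2000, **params)
        if arch == "KNN":
            return KNeighborsClassifier(**params)
        return GaussianNB(**params)


def default_specs(seed: int = 0) -> dict[str, ModelSpec]:
    return {a: ModelSpec(architecture=a, seed=seed) for a in ARCHITECTURES}


# ---------------------------------------------------------------------------
# F pre-filter
# ---------------------------------------------------------------------------

@dataclass
class PrefilterResult:
    survivors: list[str]
    f_values: pd.Series
    p_values: pd.Series
    alpha: float


def f_prefilter(
    X: pd.DataFrame, y: np.ndarray | pd.Series, alpha: float = 0.05
) -> PrefilterResult:
    """One-way ANOVA F per feature; keep features with p <= alpha.

    Features with zero variance both between and within groups have an
    undefined F and are skipped.  Expects imputed (NaN-free) input.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ParameterError("need >= 2 subjects in each of >= 2 classes")
    with np.errstate(divide="ignore", invalid="ignore"):
        f_vals, p_vals = f_classif(X.to_numpy(dtype=float), y)
    f_ser = pd.Series(f_vals, index=X.columns)
    p_ser = pd.Series(p_vals, index=X.columns)
    # a perfectly separating feature has F = inf, p = 0: retained; only a
    # feature with no variance at all (F undefined, NaN) is skipped
    keep = np.isfinite(p_vals) & (p_vals <= alpha)
    survivors = list(X.columns[keep])
    return PrefilterResult(
        survivors=survivors, f_values=f_ser, p_values=p_ser, alpha=alpha
    )


# ---------------------------------------------------------------------------
# Cross-validated F1 and forward SFS
# ---------------------------------------------------------------------------

def make_folds(
    y: np.ndarray, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold partition (reused across architectures)."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ParameterError(
            f"need >= {k} subjects per class for {k}-fold stratified CV"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _pos_label(y: np.ndarray):
    """Positive class = the lexicographically larger label (documented)."""
    return np.unique(y)[-1]


def fit_clone(estimator, X: np.ndarray, y: np.ndarray):
    """Clone and fit; KNN neighbor counts are clamped to the training size."""
    est = clone(estimator)
    if isinstance(est, KNeighborsClassifier) and est.n_neighbors > len(y):
        est.set_params(n_neighbors=len(y))
    est.fit(X, y)
    return est


def cv_f1(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
) -> float:
    """Mean F1 over the given folds (zero when a fold predicts no positives)."""
    pos = _pos_label(y)
    scores = []
    for tr, te in folds:
        est = fit_clone(estimator, X[tr], y[tr])
        pred = est.predict(X[te])
        scores.append(f1_score(y[te], pred, pos_label=pos, zero_division=0))
    return float(np.mean(scores))


@dataclass
class SelectionResult:
    """Greedy SFS path and the optimal prefix, for one architecture."""

    architecture: str
    path: list[tuple[str, float]]  # (feature added, CV F1 after addition)
    optimal_subset: list[str]
    optimal_f1: float
    prefilter: PrefilterResult | None = None


def sequential_forward_selection(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    spec: ModelSpec,
    k: int = 5,
    max_features: int | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> SelectionResult:
    """Greedy forward SFS maximising k-fold CV F1 at each step.

    The path runs until every candidate has been added (or ``max_features``
    when a shorter path is requested); the optimal subset is the shortest
    path prefix achieving the maximum CV F1.  Ties at a step are broken by
    column order.
    """
    y = np.asarray(y)
    folds = folds if folds is not None else make_folds(y, k, spec.seed)
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    est = spec.build()
    remaining = list(range(len(names)))
    chosen: list[int] = []
    path: list[tuple[str, float]] = []
    limit = len(names) if max_features is None else min(max_features, len(names))
    while remaining and len(chosen) < limit:
        best_j = None
        best_score = -np.inf
        for j in remaining:
            cols = chosen + [j]
            score = cv_f1(est, Xa[:, cols], y, folds)
            if score > best_score:  # strict: ties keep the earliest column
                best_score = score
                best_j = j
        chosen.append(best_j)
        remaining.remove(best_j)
        path.append((names[best_j], best_score))
    scores = [s for _, s in path]
    best_idx = int(np.argmax(scores))
    return SelectionResult(
        architecture=spec.architecture,
        path=path,
        optimal_subset=[name for name, _ in path[: best_idx + 1]],
        optimal_f1=float(scores[best_idx]),
    )


def grid_tune(
    spec: ModelSpec,
    subset: list[str],
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    k: int = 5,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> ModelSpec:
    """Exhaustive grid search by k-fold CV F1 on the fixed optimal subset.

    Grid combinations are evaluated in documented order (itertools.product
    over the grid's insertion order); ties keep the first combination.
    Returns a new spec with ``params`` set to the winner.
    """
    if not subset:
        raise ParameterError("cannot tune on an empty feature subset")
    y = np.asarray(y)
    folds = folds if folds is not None else make_folds(y, k, spec.seed)
    Xa = X[subset].to_numpy(dtype=float)
    keys = list(spec.grid)
    best_params = None
    best_score = -np.inf
    for combo in itertools.product(*(spec.grid[key] for key in keys)):
        params = dict(zip(keys, combo))
        try:
            score = cv_f1(spec.build(**params), Xa, y, folds)
        except ValueError:  # e.g. more neighbors than training samples
            continue
        if score > best_score:
            best_score = score
            best_params = params
    if best_params is None:
        raise ParameterError("no feasible grid combination for this cohort")
    return ModelSpec(
        architecture=spec.architecture,
        grid=spec.grid,
        params=best_params,
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# Stratified CV evaluation
# ---------------------------------------------------------------------------

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class CVReport:
    """Per-fold metrics, averaged ROC/AUC and out-of-fold predictions."""

    architecture: str
    fold_metrics: pd.DataFrame  # rows folds, cols accuracy..kappa, auc
    mean_metrics: pd.Series
    sem_metrics: pd.Series
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    auc_mean: float
    auc_sem: float
    oof: pd.DataFrame  # subject_id, fold, y_true, y_pred, score

    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture,
            "fold_metrics": self.fold_metrics.round(10).to_dict(orient="list"),
            "mean_metrics": self.mean_metrics.round(10).to_dict(),
            "sem_metrics": self.sem_metrics.round(10).to_dict(),
            "auc_mean": round(self.auc_mean, 10),
            "auc_sem": round(self.auc_sem, 10),
            "roc": {
                "fpr": [round(v, 10) for v in self.fpr_grid],
                "tpr": [round(float(v), 10) for v in self.mean_tpr],
            },
            "oof": self.oof.to_dict(orient="list"),
        }


def _scores_for(est, X: np.ndarray, pos, classes) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(X)
        return proba[:, list(est.classes_).index(pos)]
    dec = est.decision_function(X)
    return dec if classes[-1] == pos else -dec


def evaluate(
    spec: ModelSpec,
    subset: list[str],
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    k: int = 5,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
    estimator=None,
) -> CVReport:
    """Stratified k-fold evaluation on the optimal subset.

    F1 is the harmonic mean of precision and recall; kappa is Cohen's
    chance-corrected agreement.  Per-fold ROC curves are vertically
    averaged on a common 101-point FPR grid.  ``estimator`` may supply a
    pre-built (e.g. pipeline-wrapped) model instead of ``spec.build()``.
    """
    y = np.asarray(y)
    subjects = np.asarray(X.index)
    folds = folds if folds is not None else make_folds(y, k, spec.seed)
    Xa = X[subset].to_numpy(dtype=float) if subset else X.to_numpy(dtype=float)
    pos = _pos_label(y)
    classes = np.unique(y)
    base_est = estimator if estimator is not None else spec.build()

    rows = []
    tprs = []
    oof_parts = []
    for fold_id, (tr, te) in enumerate(folds):
        if len(np.unique(y[te])) < 2:
            raise StratificationError(
                f"fold {fold_id} has a single class in its test set"
            )
        est = fit_clone(base_est, Xa[tr], y[tr])
        pred = est.predict(Xa[te])
        score = _scores_for(est, Xa[te], pos, classes)
        rows.append(
            {
                "accuracy": accuracy_score(y[te], pred),
                "precision": precision_score(
                    y[te], pred, pos_label=pos, zero_division=0
                ),
                "recall": recall_score(y[te], pred, pos_label=pos, zero_division=0),
                "f1": f1_score(y[te], pred, pos_label=pos, zero_division=0),
                "kappa": cohen_kappa_score(y[te], pred),
                "auc": roc_auc_score((y[te] == pos).astype(int), score),
            }
        )
        fpr, tpr, _ = roc_curve((y[te] == pos).astype(int), score)
        interp = np.interp(FPR_GRID, fpr, tpr)
        interp[0] = 0.0
        tprs.append(interp)
        oof_parts.append(
            pd.DataFrame(
                {
                    "subject_id": subjects[te],
                    "fold": fold_id,
                    "y_true": y[te],
                    "y_pred": pred,
                    "score": score,
                }
            )
        )
    fold_metrics = pd.DataFrame(rows)
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    aucs = fold_metrics["auc"].to_numpy()
    sem = fold_metrics.sem(ddof=1)
    return CVReport(
        architecture=spec.architecture,
        fold_metrics=fold_metrics,
        mean_metrics=fold_metrics.mean(),
        sem_metrics=sem,
        fpr_grid=FPR_GRID.copy(),
        mean_tpr=mean_tpr,
        auc_mean=float(aucs.mean()),
        auc_sem=float(stats.sem(aucs, ddof=1)),
        oof=pd.concat(oof_parts, ignore_index=True),
    )


def nested_evaluate(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    k: int = 5,
    alpha: float = 0.05,
    max_features: int | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVReport:
    """Leakage-safe nested CV: scaling, pre-filter and SFS fit per fold.

    Every outer training fold gets its own min-max scaling, ANOVA F
    pre-filter and greedy SFS (inner folds drawn from the training fold
    only); the outer test fold is touched only for prediction.  On pure
    null cohorts this concentrates at chance, unlike the single global
    selection, whose optimism can thereby be measured.
    """
    from sklearn.preprocessing import MinMaxScaler

    y = np.asarray(y)
    subjects = np.asarray(X.index)
    folds = folds if folds is not None else make_folds(y, k, spec.seed)
    pos = _pos_label(y)
    classes = np.unique(y)

    rows, tprs, oof_parts = [], [], []
    for fold_id, (tr, te) in enumerate(folds):
        if len(np.unique(y[te])) < 2:
            raise StratificationError(
                f"fold {fold_id} has a single class in its test set"
            )
        scaler = MinMaxScaler().fit(X.iloc[tr])
        Xtr = pd.DataFrame(
            scaler.transform(X.iloc[tr]), columns=X.columns, index=X.index[tr]
        )
        Xte = pd.DataFrame(
            scaler.transform(X.iloc[te]), columns=X.columns, index=X.index[te]
        )
        pre = f_prefilter(Xtr, y[tr], alpha=alpha)
        survivors = pre.survivors or [pre.p_values.idxmin()]
        inner_k = min(k, int(np.unique(y[tr], return_counts=True)[1].min()))
        sel = sequential_forward_selection(
            Xtr[survivors], y[tr], spec, k=inner_k, max_features=max_features,
            folds=make_folds(y[tr], inner_k, spec.seed),
        )
        est = fit_clone(spec.build(), Xtr[sel.optimal_subset].to_numpy(), y[tr])
        Xte_a = Xte[sel.optimal_subset].to_numpy()
        pred = est.predict(Xte_a)
        score = _scores_for(est, Xte_a, pos, classes)
        rows.append(
            {
                "accuracy": accuracy_score(y[te], pred),
                "precision": precision_score(y[te], pred, pos_label=pos, zero_division=0),
                "recall": recall_score(y[te], pred, pos_label=pos, zero_division=0),
                "f1": f1_score(y[te], pred, pos_label=pos, zero_division=0),
                "kappa": cohen_kappa_score(y[te], pred),
                "auc": roc_auc_score((y[te] == pos).astype(int), score),
            }
        )
        fpr, tpr, _ = roc_curve((y[te] == pos).astype(int), score)
        interp = np.interp(FPR_GRID, fpr, tpr)
        interp[0] = 0.0
        tprs.append(interp)
        oof_parts.append(
            pd.DataFrame(
                {
                    "subject_id": subjects[te],
                    "fold": fold_id,
                    "y_true": y[te],
                    "y_pred": pred,
                    "score": score,
                }
            )
        )
    fold_metrics = pd.DataFrame(rows)
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    aucs = fold_metrics["auc"].to_numpy()
    return CVReport(
        architecture=spec.architecture,
        fold_metrics=fold_metrics,
        mean_metrics=fold_metrics.mean(),
        sem_metrics=fold_metrics.sem(ddof=1),
        fpr_grid=FPR_GRID.copy(),
        mean_tpr=mean_tpr,
        auc_mean=float(aucs.mean()),
        auc_sem=float(stats.sem(aucs, ddof=1)),
        oof=pd.concat(oof_parts, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# Task-set comparison
# ---------------------------------------------------------------------------

TASK_SET_PAIRS = (
    ("static", "static_active"),
    ("active", "static_active"),
    ("active", "static"),
)


def compare_task_conditions(
    reports: dict[tuple[str, str], CVReport],
    metric: str = "f1",
) -> pd.DataFrame:
    """Pairwise task-set comparisons of fold-level metrics.

    Fold-level values of ``metric`` are modelled with task set and
    architecture as fixed effects (architecture blocks the paired design);
    the task-set p-value is reported against the Bonferroni threshold
    0.05/3 for the three comparisons.
    """
    long = []
    for (task_set, arch), rep in reports.items():
        for v in rep.fold_metrics[metric]:
            long.append({"task_set": task_set, "architecture": arch, "value": v})
    df = pd.DataFrame(long)
    rows = []
    for a, b in TASK_SET_PAIRS:
        sub = df[df["task_set"].isin([a, b])]
        if sub["task_set"].nunique() < 2:
            continue
        archs_a = set(sub[sub.task_set == a]["architecture"])
        archs_b = set(sub[sub.task_set == b]["architecture"])
        if archs_a != archs_b:
            raise ParameterError(
                f"unbalanced report sets for comparison {a} vs {b}"
            )
        if sub["value"].var(ddof=1) == 0:
            p = 1.0  # identical metric distributions: no evidence
        else:
            model = smf.ols("value ~ C(task_set) + C(architecture)", data=sub).fit()
            table = anova_lm(model, typ=2)
            p = float(table.loc["C(task_set)", "PR(>F)"])
        means = sub.groupby("task_set")["value"].mean()
        rows.append(
            {
                "comparison": f"{a} vs {b}",
                "mean_" + a: float(means[a]),
                "mean_" + b: float(means[b]),
                "p_value": p,
                "threshold": round(BONFERRONI_ALPHA, 3),
                "significant": bool(p < BONFERRONI_ALPHA),
            }
        )
    return pd.DataFrame(rows)
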