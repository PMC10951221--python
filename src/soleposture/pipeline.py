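"""End-to-end experiments: ingest/simulate -> features -> selection ->
models -> interpretation, over the three classifications and three task
sets.

A single experiment (:func:`run_experiment`) runs one binary
classification (PD vs young controls, PD vs age-matched controls, or PD
fallers vs non-fallers) on one task set (static, active, or
static+active): feature-table assembly at 12 Hz, median imputation,
min-max normalization, the ANOVA F pre-filter, forward SFS and grid
tuning per architecture, stratified 5-fold evaluation, and the
interpretation block (common features, per-model top Shapley features,
commonly misclassified subjects, per-group z-scores, correlations).

:func:`run_all` sweeps the classification x task-set grid, aggregates a
summary table of mean +/- SEM metrics, and intersects common and
top-Shapley features across task sets into the key-feature set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ParameterError
from .features import FeatureTable, build_feature_table, minmax_normalize
from .insole_io import InsoleRecording, SubjectMeta, TASK_SETS
from .interpret import (
    KeyFeatureSet,
    common_features,
    feature_correlation,
    group_zscores,
    key_features,
    misclassified_subjects,
    shapley_values,
)
from .selection import (
    ARCHITECTURES,
    CVReport,
    ModelSpec,
    SelectionResult,
    evaluate,
    f_prefilter,
    grid_tune,
    make_folds,
    nested_evaluate,
    sequential_forward_selection,
)

logger = logging.getLogger("soleposture")

CLASSIFICATIONS = {
    "pd_vs_young": ("young_control", "pd"),
    "pd_vs_age_matched": ("age_matched_control", "pd"),
    "faller_vs_nonfaller": ("pd_nonfaller", "pd_faller"),
}


def classification_labels(
    meta: dict[str, SubjectMeta], classification: str
) -> pd.Series:
    """Subject -> class label for one of the three named classifications."""
    if classification not in CLASSIFICATIONS:
        raise ParameterError(
            f"classification must be one of {sorted(CLASSIFICATIONS)}"
        )
    out = {}
    for sid, m in meta.items():
        if classification == "faller_vs_nonfaller":
            if m.group == "pd" and m.faller is not None:
                out[sid] = "pd_faller" if m.faller else "pd_nonfaller"
        else:
            neg, pos = CLASSIFICATIONS[classification]
            if m.group in (neg, pos):
                out[sid] = m.group
    return pd.Series(out, name="label")


@dataclass
class ExperimentConfig:
    """Knobs for one selection-classification-interpretation experiment."""

    classification: str = "pd_vs_age_matched"
    task_set: str = "static_active"  # static | active | static_active
    seed: int = 0
    k: int = 5
    alpha: float = 0.05
    sfs_max_features: int | None = None  # None: full greedy path
    leakage_mode: str = "paper_faithful"  # | leakage_safe
    target_rate: float = 12.0
    architectures: tuple[str, ...] = ARCHITECTURES
    shap_permutations: int = 50

    def __post_init__(self) -> None:
        if self.task_set not in TASK_SETS:
            raise ParameterError(f"task_set must be one of {sorted(TASK_SETS)}")
        if self.leakage_mode not in ("paper_faithful", "leakage_safe"):
            raise ParameterError("leakage_mode must be paper_faithful|leakage_safe")


@dataclass
class ExperimentBundle:
    """Everything one experiment produced."""

    config: ExperimentConfig
    n_subjects: int
    n_features: int
    survivors: list[str]
    selections: dict[str, SelectionResult]
    tuned: dict[str, ModelSpec]
    reports: dict[str, CVReport]
    common: list[str]
    top_shapley: dict[str, str]  # architecture -> top feature
    misclassified: list[str]
    zscores: pd.DataFrame | None
    correlations: pd.DataFrame | None

    def best_architecture(self) -> str:
        return max(self.reports, key=lambda a: self.reports[a].auc_mean)

    def summary(self) -> pd.DataFrame:
        rows = []
        for arch, rep in self.reports.items():
            row = {"architecture": arch}
            for m in ("accuracy", "precision", "recall", "f1", "kappa", "auc"):
                row[f"{m}_mean"] = float(rep.mean_metrics[m])
                row[f"{m}_sem"] = float(rep.sem_metrics[m])
            rows.append(row)
        df = pd.DataFrame(rows)
        df.insert(0, "task_set", self.config.task_set)
        df.insert(0, "classification", self.config.classification)
        return df

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "version": __version__,
            "n_subjects": self.n_subjects,
            "n_features": self.n_features,
            "survivors": list(self.survivors),
            "selections": {
                a: {
                    "path": [[n, round(f, 10)] for n, f in s.path],
                    "optimal_subset": s.optimal_subset,
                    "optimal_f1": round(s.optimal_f1, 10),
                }
                for a, s in self.selections.items()
            },
            "tuned_params": {a: t.params for a, t in self.tuned.items()},
            "reports": {a: r.to_dict() for a, r in self.reports.items()},
            "common_features": self.common,
            "top_shapley": self.top_shapley,
            "misclassified": self.misclassified,
            "zscores": None
            if self.zscores is None
            else self.zscores.round(10).to_dict(),
            "correlations": None
            if self.correlations is None
            else self.correlations.round(10).to_dict(),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def prepare_table(
    recordings: list[InsoleRecording],
    meta: dict[str, SubjectMeta],
    config: ExperimentConfig,
    labels: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix (flat column names) and labels for one experiment."""
    labels = labels if labels is not None else classification_labels(
        meta, config.classification
    )
    keep = [r for r in recordings if r.subject_id in labels.index]
    table = build_feature_table(
        keep,
        meta=meta,
        tasks=TASK_SETS[config.task_set],
        target_rate=config.target_rate,
    )
    table = FeatureTable(
        data=table.data.loc[labels.index.intersection(table.data.index)],
        labels=labels,
    )
    table = table.impute_median()
    if config.leakage_mode == "paper_faithful":
        table = minmax_normalize(table)
    X = table.flat()
    y = labels.loc[X.index]
    return X, y


def run_experiment(
    recordings: list[InsoleRecording],
    meta: dict[str, SubjectMeta],
    config: ExperimentConfig,
    labels: pd.Series | None = None,
    X: pd.DataFrame | None = None,
    y: pd.Series | None = None,
) -> ExperimentBundle:
    """Execute the full stack for one classification on one task set.

    ``X``/``y`` may supply a precomputed feature matrix (flat column
    names) to skip re-ingestion, e.g. when sweeping task sets over the
    same cohort.
    """
    if X is None or y is None:
        X, y = prepare_table(recordings, meta, config, labels)
    logger.info(
        "experiment %s/%s: %d subjects, %d features",
        config.classification, config.task_set, len(X), X.shape[1],
    )
    pre = f_prefilter(X, y, alpha=config.alpha)
    survivors = pre.survivors
    if not survivors:  # degenerate null cohort: keep the single best feature
        survivors = [pre.p_values.idxmin()]
        logger.warning("pre-filter removed every feature; keeping best F only")
    Xs = X[survivors]
    yv = y.to_numpy()
    folds = make_folds(yv, config.k, config.seed)

    selections: dict[str, SelectionResult] = {}
    tuned: dict[str, ModelSpec] = {}
    reports: dict[str, CVReport] = {}
    tops: dict[str, str] = {}
    for arch in config.architectures:
        spec = ModelSpec(architecture=arch, seed=config.seed)
        sel = sequential_forward_selection(
            Xs, yv, spec, k=config.k,
            max_features=config.sfs_max_features, folds=folds,
        )
        sel.prefilter = pre
        selections[arch] = sel
        tuned[arch] = grid_tune(spec, sel.optimal_subset, Xs, yv,
                                k=config.k, folds=folds)
        if config.leakage_mode == "leakage_safe":
            reports[arch] = nested_evaluate(
                tuned[arch], X, yv, k=config.k, alpha=config.alpha,
                max_features=config.sfs_max_features, folds=folds,
            )
        else:
            reports[arch] = evaluate(
                tuned[arch], sel.optimal_subset, Xs, yv,
                k=config.k, folds=folds,
            )
        tops[arch] = _fold_top_shapley(
            tuned[arch], sel.optimal_subset, Xs, yv, folds, config
        )
        logger.info(
            "  %s: |subset|=%d cv_f1=%.3f auc=%.3f top_shap=%s",
            arch, len(sel.optimal_subset), sel.optimal_f1,
            reports[arch].auc_mean, tops[arch],
        )

    common = common_features(list(selections.values()))
    mis = misclassified_subjects(list(reports.values()))
    zs = group_zscores(X, y, common) if common else None
    corr = feature_correlation(X, common) if len(common) > 1 else None
    return ExperimentBundle(
        config=config,
        n_subjects=len(X),
        n_features=X.shape[1],
        survivors=survivors,
        selections=selections,
        tuned=tuned,
        reports=reports,
        common=common,
        top_shapley=tops,
        misclassified=mis,
        zscores=zs,
        correlations=corr,
    )


def _fold_top_shapley(
    spec: ModelSpec,
    subset: list[str],
    X: pd.DataFrame,
    y: np.ndarray,
    folds,
    config: ExperimentConfig,
) -> str:
    """Top Shapley feature: highest mean |phi| pooled over all folds.

    Each fold's tuned model is explained on its test rows with that fold's
    training rows as background — the model never explains a subject it
    trained on.
    """
    if len(subset) == 1:
        return subset[0]
    from .selection import fit_clone

    mean_abs = pd.Series(0.0, index=subset)
    for tr, te in folds:
        est = fit_clone(spec.build(), X[subset].to_numpy()[tr], y[tr])
        res = shapley_values(
            est,
            X[subset].iloc[te],
            X[subset].iloc[tr],
            n_permutations=config.shap_permutations,
            seed=config.seed,
            max_exact=10,
        )
        mean_abs = mean_abs.add(res.mean_abs * len(te), fill_value=0.0)
    return str(mean_abs.idxmax())


def run_all(
    recordings: list[InsoleRecording],
    meta: dict[str, SubjectMeta],
    base_config: ExperimentConfig | None = None,
    classifications: tuple[str, ...] = tuple(CLASSIFICATIONS),
    task_sets: tuple[str, ...] = tuple(TASK_SETS),
) -> dict:
    """Sweep classifications x task sets; aggregate summaries and key features.

    Classifications the cohort cannot support (a missing group, or fewer
    subjects than folds) are recorded as explicit skips.  Returns a dict
    with ``bundles`` (nested classification -> task_set), ``summary`` (one
    row per classification/task set/architecture) and ``key_features``
    (per classification, the :class:`KeyFeatureSet` across task sets).
    """
    from dataclasses import replace as dc_replace

    base = base_config or ExperimentConfig()
    bundles: dict[str, dict[str, ExperimentBundle]] = {}
    skips: list[dict] = []
    summaries = []
    keysets: dict[str, KeyFeatureSet] = {}
    for clf in classifications:
        labels = classification_labels(meta, clf)
        counts = labels.value_counts()
        if len(counts) < 2 or counts.min() < base.k:
            skips.append({
                "classification": clf,
                "reason": f"insufficient subjects per class: {counts.to_dict()}",
            })
            continue
        bundles[clf] = {}
        common_by_ts: dict[str, list[str]] = {}
        tops_by_ts: dict[str, list[str]] = {}
        for ts in task_sets:
            config = dc_replace(base, classification=clf, task_set=ts)
            bundle = run_experiment(recordings, meta, config, labels=labels)
            bundles[clf][ts] = bundle
            summaries.append(bundle.summary())
            common_by_ts[ts] = bundle.common
            tops_by_ts[ts] = list(bundle.top_shapley.values())
        keysets[clf] = key_features(common_by_ts, tops_by_ts)
    summary = (
        pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    )
    return {
        "bundles": bundles,
        "summary": summary,
        "key_features": keysets,
        "skipped": skips,
    }
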