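"""F pre-filter, SFS vs brute force, tuning, CV metrics, task comparisons."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.metrics import f1_score

from soleposture.exceptions import ParameterError
from soleposture.selection import (
    BONFERRONI_ALPHA,
    CVReport,
    ModelSpec,
    compare_task_conditions,
    evaluate,
    f_prefilter,
    grid_tune,
    make_folds,
    sequential_forward_selection,
)


def _table(arrays: dict, labels) -> tuple[pd.DataFrame, np.ndarray]:
    X = pd.DataFrame(arrays)
    return X, np.asarray(labels)


class TestPrefilter:
    def test_hand_computed_anova(self):
        # {1,2,3} vs {4,5,6}: MSB = 13.5, MSW = 1 -> F = 13.5
        X, y = _table({"f": [1, 2, 3, 4, 5, 6]}, ["a"] * 3 + ["b"] * 3)
        res = f_prefilter(X, y)
        assert res.f_values["f"] == pytest.approx(13.5)
        assert res.p_values["f"] == pytest.approx(0.0213, abs=2e-3)
        assert res.survivors == ["f"]

    def test_identical_feature_removed(self):
        X, y = _table(
            {"same": [1.0] * 6 + [1.0] * 6, "sep": [0.0] * 6 + [1.0] * 6},
            ["a"] * 6 + ["b"] * 6,
        )
        res = f_prefilter(X, y)
        assert "same" not in res.survivors and "sep" in res.survivors

    def test_null_features_retained_at_alpha_rate(self):
        rng = np.random.default_rng(0)
        fractions = []
        for _ in range(50):
            X = pd.DataFrame(rng.normal(size=(40, 200)))
            X.columns = [f"f{i}" for i in range(200)]
            y = np.r_[np.zeros(20), np.ones(20)]
            fractions.append(len(f_prefilter(X, y).survivors) / 200)
        assert np.mean(fractions) == pytest.approx(0.05, abs=0.02)

    def test_needs_two_classes(self):
        X, y = _table({"f": [1, 2, 3]}, ["a", "a", "a"])
        with pytest.raises(ParameterError):
            f_prefilter(X, y)


def brute_force_sfs(X, y, spec, folds):
    """Independent greedy recomputation using sklearn primitives only."""
    names = list(X.columns)
    chosen, path = [], []
    remaining = names[:]
    pos = np.unique(y)[-1]
    while remaining:
        scored = []
        for name in remaining:
            cols = chosen + [name]
            f1s = []
            for tr, te in folds:
                est = clone(spec.build())
                est.fit(X[cols].to_numpy()[tr], y[tr])
                f1s.append(
                    f1_score(
                        y[te], est.predict(X[cols].to_numpy()[te]),
                        pos_label=pos, zero_division=0,
                    )
                )
            scored.append((float(np.mean(f1s)), name))
        best_score = max(s for s, _ in scored)
        best_name = next(n for s, n in scored if s == best_score)
        chosen.append(best_name)
        remaining.remove(best_name)
        path.append((best_name, best_score))
    return path


class TestSFS:
    @staticmethod
    def _separable(seed=0, n=20, n_null=5):
        rng = np.random.default_rng(seed)
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        cols = {"signal": y * 10 + rng.normal(0, 0.5, n)}
        for i in range(n_null):
            cols[f"null{i}"] = rng.normal(size=n)
        return pd.DataFrame(cols), y

    def test_perfect_feature_selected_first(self):
        X, y = self._separable()
        spec = ModelSpec("LR", seed=0)
        res = sequential_forward_selection(X, y, spec)
        assert res.path[0][0] == "signal"
        assert res.optimal_f1 == 1.0
        assert res.optimal_subset == ["signal"]

    def test_path_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            {
                "a": rng.normal(size=15),
                "b": rng.normal(size=15),
                "c": rng.normal(size=15),
            }
        )
        y = np.r_[np.zeros(7), np.ones(8)]
        X["b"] += y * 1.5
        spec = ModelSpec("GNB", seed=1)
        folds = make_folds(y, 5, spec.seed)
        res = sequential_forward_selection(X, y, spec, folds=folds)
        oracle = brute_force_sfs(X, y, spec, folds)
        assert [n for n, _ in res.path] == [n for n, _ in oracle]
        for (_, s1), (_, s2) in zip(res.path, oracle):
            assert s1 == pytest.approx(s2, abs=1e-12)
        best = int(np.argmax([s for _, s in oracle]))
        assert res.optimal_subset == [n for n, _ in oracle[: best + 1]]

    def test_duplicate_column_tie_keeps_first(self):
        X, y = self._separable()
        X["signal_copy"] = X["signal"]
        cols = ["signal", "signal_copy"] + [c for c in X if "null" in c]
        res = sequential_forward_selection(X[cols], y, ModelSpec("LR", seed=0))
        assert res.path[0][0] == "signal"

    def test_fewer_subjects_than_folds_rejected(self):
        X = pd.DataFrame({"f": np.arange(6.0)})
        y = np.r_[np.zeros(3), np.ones(3)]
        with pytest.raises(ParameterError):
            sequential_forward_selection(X, y, ModelSpec("LR"), k=5)


class TestGridTune:
    def test_single_point_grid_unchanged(self):
        X, y = TestSFS._separable()
        spec = ModelSpec("LR", grid={"C": [1.0]}, seed=0)
        tuned = grid_tune(spec, ["signal"], X, y)
        assert tuned.params == {"C": 1.0}

    def test_knn_prefers_local_neighborhood(self):
        # tight clusters: 1-NN fits, 50-NN (more than a class) cannot
        rng = np.random.default_rng(0)
        centers = np.repeat(np.arange(8) * 10.0, 8)
        y = np.tile(np.r_[np.zeros(4), np.ones(4)], 8)
        X = pd.DataFrame({"f": centers + rng.normal(0, 0.1, 64), "g": y + rng.normal(0, 0.05, 64)})
        spec = ModelSpec("KNN", grid={"n_neighbors": [1, 50]}, seed=0)
        tuned = grid_tune(spec, ["f", "g"], X, y)
        assert tuned.params["n_neighbors"] == 1

    def test_deterministic(self):
        X, y = TestSFS._separable()
        spec = ModelSpec("SVM", seed=4)
        t1 = grid_tune(spec, ["signal"], X, y)
        t2 = grid_tune(spec, ["signal"], X, y)
        assert t1.params == t2.params

    def test_empty_subset_rejected(self):
        X, y = TestSFS._separable()
        with pytest.raises(ParameterError):
            grid_tune(ModelSpec("LR"), [], X, y)


class TestEvaluate:
    def test_separable_cohort_perfect_metrics(self):
        X, y = TestSFS._separable(n=30)
        for arch in ("SVM", "RF", "LR", "KNN", "GNB"):
            rep = evaluate(ModelSpec(arch, seed=0), ["signal"], X, y)
            assert rep.mean_metrics["accuracy"] == 1.0
            assert rep.auc_mean == 1.0
            assert rep.mean_metrics["kappa"] == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"f": rng.normal(size=60), "g": rng.normal(size=60)})
        y = rng.permutation(np.r_[np.zeros(30), np.ones(30)])
        rep = evaluate(ModelSpec("LR", seed=1), ["f", "g"], X, y)
        assert 0.35 <= rep.auc_mean <= 0.65

    def test_out_of_fold_coverage_total(self):
        X, y = TestSFS._separable(n=20)
        rep = evaluate(ModelSpec("GNB", seed=0), ["signal"], X, y)
        assert sorted(rep.oof["subject_id"]) == sorted(X.index)
        assert rep.oof["fold"].nunique() == 5

    def test_constant_predictor_closed_form_kappa(self):
        # all-one-class predictions on a balanced set: accuracy 0.5, kappa 0
        from sklearn.dummy import DummyClassifier

        X, y = TestSFS._separable(n=20)
        spec = ModelSpec("GNB", seed=0)
        rep = evaluate(
            spec, ["signal"], X, y,
            estimator=DummyClassifier(strategy="constant", constant=1),
        )
        assert rep.mean_metrics["accuracy"] == 0.5
        assert rep.mean_metrics["kappa"] == 0.0


class TestCompareTaskConditions:
    @staticmethod
    def _reports(shift: float, seed=0) -> dict:
        rng = np.random.default_rng(seed)
        reports = {}
        for ts, delta in (("static", 0.0), ("static_active", shift), ("active", 0.0)):
            for arch in ("LR", "GNB"):
                fm = pd.DataFrame(
                    {
                        "f1": np.clip(0.7 + delta + rng.normal(0, 0.01, 5), 0, 1),
                        "accuracy": np.full(5, 0.7),
                        "precision": np.full(5, 0.7),
                        "recall": np.full(5, 0.7),
                        "kappa": np.full(5, 0.4),
                        "auc": np.full(5, 0.8),
                    }
                )
                reports[(ts, arch)] = CVReport(
                    architecture=arch,
                    fold_metrics=fm,
                    mean_metrics=fm.mean(),
                    sem_metrics=fm.sem(),
                    fpr_grid=np.linspace(0, 1, 101),
                    mean_tpr=np.linspace(0, 1, 101),
                    auc_mean=0.8,
                    auc_sem=0.01,
                    oof=pd.DataFrame(
                        {"subject_id": [], "fold": [], "y_true": [],
                         "y_pred": [], "score": []}
                    ),
                )
        return reports

    def test_threshold_value(self):
        assert round(BONFERRONI_ALPHA, 3) == 0.017

    def test_null_shift_not_significant(self):
        table = compare_task_conditions(self._reports(0.0), "f1")
        row = table[table.comparison == "static vs static_active"].iloc[0]
        assert row.p_value > BONFERRONI_ALPHA
        assert not row.significant

    def test_large_shift_significant(self):
        table = compare_task_conditions(self._reports(0.2), "f1")
        row = table[table.comparison == "static vs static_active"].iloc[0]
        assert row.p_value < BONFERRONI_ALPHA
        assert row.significant
        assert row.threshold == 0.017
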