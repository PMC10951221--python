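"""Shapley axioms, common/key feature rules, misclassification, z-scores."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from soleposture.interpret import (
    common_features,
    feature_correlation,
    group_zscores,
    key_features,
    misclassified_subjects,
    shapley_values,
)
from soleposture.selection import CVReport, SelectionResult


def _sel(subset):
    return SelectionResult(
        architecture="LR", path=[(n, 1.0) for n in subset],
        optimal_subset=list(subset), optimal_f1=1.0,
    )


class TestCommonFeatures:
    def test_boundary_counts(self):
        subsets = [["a", "b"], ["a"], ["a", "c"], ["b", "c"], ["c"]]
        # counts: a=3, b=2, c=3
        out = common_features([_sel(s) for s in subsets])
        assert set(out) == {"a", "c"}

    def test_all_five_included_two_excluded(self):
        subsets = [["x", "y"]] * 2 + [["x"]] * 3
        out = common_features([_sel(s) for s in subsets])
        assert out == ["x"]

    def test_matches_counting_oracle_randomized(self):
        rng = np.random.default_rng(0)
        names = [f"f{i}" for i in range(12)]
        for _ in range(20):
            subsets = [
                list(rng.choice(names, size=rng.integers(1, 8), replace=False))
                for _ in range(5)
            ]
            out = common_features([_sel(s) for s in subsets])
            counts = {}
            for s in subsets:
                for n in set(s):
                    counts[n] = counts.get(n, 0) + 1
            expected = {n for n, c in counts.items() if c >= 3}
            assert set(out) == expected


class _LinearProbModel:
    """Deterministic model with decision_function w . x."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def decision_function(self, X):
        return np.asarray(X) @ self.w


class TestShapley:
    def test_null_player_axiom(self):
        model = _LinearProbModel([2.0, 0.0, -1.0])
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(6, 3)), columns=["a", "b", "c"])
        bg = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        res = shapley_values(model, X, bg)
        np.testing.assert_array_equal(res.values["b"].to_numpy(), 0.0)

    def test_linear_model_closed_form(self):
        # additive model: phi_j = w_j (x_j - background mean_j)
        w = [2.0, 3.0]
        model = _LinearProbModel(w)
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(5, 2)), columns=["x1", "x2"])
        bg = pd.DataFrame(rng.normal(size=(20, 2)), columns=["x1", "x2"])
        res = shapley_values(model, X, bg)
        for j, name in enumerate(["x1", "x2"]):
            expected = w[j] * (X[name] - bg[name].mean())
            np.testing.assert_allclose(res.values[name], expected, atol=1e-10)

    def test_local_accuracy_fitted_model(self):
        rng = np.random.default_rng(2)
        Xtr = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        ytr = (Xtr["a"] + Xtr["c"] > 0).astype(int)
        model = RandomForestClassifier(n_estimators=30, random_state=0)
        model.fit(Xtr, ytr)
        Xe = Xtr.iloc[:5]
        res = shapley_values(model, Xe, Xtr)
        fx = model.predict_proba(Xe)[:, -1]
        np.testing.assert_allclose(
            res.base_value + res.values.sum(axis=1), fx, atol=1e-6
        )

    def test_sampling_consistent_with_exact(self):
        model = _LinearProbModel([1.0, -2.0, 0.5])
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(4, 3)), columns=["a", "b", "c"])
        bg = pd.DataFrame(rng.normal(size=(8, 3)), columns=["a", "b", "c"])
        exact = shapley_values(model, X, bg)
        sampled = shapley_values(model, X, bg, max_exact=0, n_permutations=400, seed=0)
        assert sampled.method == "sampling"
        np.testing.assert_allclose(
            sampled.values.to_numpy(), exact.values.to_numpy(), atol=0.05
        )

    def test_top_feature_is_strongest_weight(self):
        model = _LinearProbModel([0.1, 5.0])
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(8, 2)), columns=["weak", "strong"])
        res = shapley_values(model, X, X)
        assert res.top_feature == "strong"


class TestKeyFeatures:
    def test_disjoint_sets_empty(self):
        ks = key_features(
            common={"static": ["a", "b"]}, top_shapley={"static": ["c"]}
        )
        assert ks.key == []

    def test_constructed_overlap(self):
        ks = key_features(
            common={"static": ["a", "b"], "active": ["c", "d"]},
            top_shapley={"static": ["b", "e"], "active": ["d"]},
        )
        assert ks.key == ["b", "d"]
        assert all(k in sum(ks.common.values(), []) for k in ks.key)


class TestMisclassification:
    @staticmethod
    def _report(wrong_ids, all_ids=("s0", "s1", "s2", "s3")):
        oof = pd.DataFrame(
            {
                "subject_id": all_ids,
                "fold": range(len(all_ids)),
                "y_true": [0] * len(all_ids),
                "y_pred": [1 if s in wrong_ids else 0 for s in all_ids],
                "score": [0.5] * len(all_ids),
            }
        )
        return CVReport(
            architecture="LR", fold_metrics=pd.DataFrame({"f1": [1.0]}),
            mean_metrics=pd.Series(), sem_metrics=pd.Series(),
            fpr_grid=np.zeros(1), mean_tpr=np.zeros(1),
            auc_mean=1.0, auc_sem=0.0, oof=oof,
        )

    def test_three_of_five_boundary(self):
        reports = [self._report({"s1"})] * 3 + [self._report(set())] * 2
        assert misclassified_subjects(reports) == ["s1"]
        reports = [self._report({"s1"})] * 2 + [self._report(set())] * 3
        assert misclassified_subjects(reports) == []

    def test_all_models_perfect(self):
        assert misclassified_subjects([self._report(set())] * 5) == []


class TestZScoresAndCorrelation:
    def test_identical_groups_zero(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        labels = ["a"] * 3 + ["b"] * 3
        z = group_zscores(X, labels, ["f"])
        np.testing.assert_allclose(z["f"], 0.0, atol=1e-12)

    def test_hand_computed_six_subjects(self):
        vals = np.array([1.0, 2.0, 3.0, 5.0, 6.0, 7.0])
        X = pd.DataFrame({"f": vals})
        labels = ["a"] * 3 + ["b"] * 3
        z = group_zscores(X, labels, ["f"])
        pooled = (vals - vals.mean()) / vals.std(ddof=1)
        assert z.loc["a", "f"] == pytest.approx(pooled[:3].mean())
        assert z.loc["b", "f"] == pytest.approx(pooled[3:].mean())
        assert z.loc["a", "f"] == pytest.approx(-z.loc["b", "f"])

    def test_correlation_matrix_properties(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            {
                "u": rng.normal(size=200),
                "v": rng.normal(size=200),
            }
        )
        X["w"] = 2 * X["u"] + 1  # exactly linear
        corr = feature_correlation(X, ["u", "v", "w"])
        assert corr.loc["u", "u"] == pytest.approx(1.0)
        assert corr.loc["u", "w"] == pytest.approx(1.0)
        assert abs(corr.loc["u", "v"]) < 0.2
        np.testing.assert_allclose(corr, corr.T)
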