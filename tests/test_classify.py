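from itertools import combinations
from math import factorial

import numpy as np
import pytest
from xgboost import XGBClassifier

from otusynth.classify import (
    AttributionReport,
    compare_models_cv,
    export_plot_data,
    fit_final_and_evaluate,
    make_model,
    shap_attributions,
    stratified_split,
)
from otusynth.fixtures import FixtureConfig, make_fixture


def _exhaustive_shapley(f, x, background, p):
    """Independent oracle: exact interventional Shapley by 2^p enumeration."""
    B = np.atleast_2d(background)

    def v(S):
        Z = B.copy()
        S = list(S)
        if S:
            Z[:, S] = x[S]
        return f(Z).mean()

    phi = np.zeros(p)
    feats = list(range(p))
    for i in feats:
        rest = [j for j in feats if j != i]
        for r in range(len(rest) + 1):
            for S in combinations(rest, r):
                w = factorial(len(S)) * factorial(p - len(S) - 1) / factorial(p)
                phi[i] += w * (v(S + (i,)) - v(S))
    return phi


class TestStratifiedSplit:
    @pytest.fixture(scope="class")
    def dataset(self):
        table, meta, _ = make_fixture(
            FixtureConfig(
                seed=9,
                n_features=20,
                group_sizes={
                    (c, s): 30 for c in ("AP", "CRC") for s in ("stool", "biopsy", "saliva")
                },
            )
        )
        return table, meta

    def test_counts_near_ratio_per_stratum(self, dataset):
        table, meta = dataset
        plan = stratified_split(table, meta, holdout_fraction=0.2, seed=0)
        assert len(plan.holdout_ids) == 36  # 6 strata x 30 x 0.2
        assert len(plan.train_ids) == 144
        meta_by_id = {m.sample_id: m for m in meta}
        for cond in ("AP", "CRC"):
            for spec in ("stool", "biopsy", "saliva"):
                n_h = sum(
                    1
                    for s in plan.holdout_ids
                    if meta_by_id[s].condition == cond and meta_by_id[s].specimen == spec
                )
                assert abs(n_h - 6) <= 1

    def test_disjoint_and_exhaustive(self, dataset):
        table, meta = dataset
        plan = stratified_split(table, meta, seed=1)
        ids = plan.train_ids + plan.holdout_ids
        assert len(ids) == len(set(ids)) == table.n_samples

    def test_zero_holdout(self, dataset):
        table, meta = dataset
        plan = stratified_split(table, meta, holdout_fraction=0.0, seed=0)
        assert plan.holdout_ids == []

    def test_same_seed_same_plan(self, dataset):
        table, meta = dataset
        a = stratified_split(table, meta, seed=5)
        b = stratified_split(table, meta, seed=5)
        assert a.train_ids == b.train_ids and a.holdout_ids == b.holdout_ids

    def test_small_stratum_rejected(self, toy_table, toy_meta):
        with pytest.raises(ValueError, match="stratum"):
            stratified_split(toy_table, toy_meta)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    n = 60
    X = np.abs(np.vstack([rng.normal(2, 1, (n, 6)), rng.normal(6, 1, (n, 6))]))
    conds = ["AP"] * n + ["CRC"] * n
    return X, conds


class TestModelComparison:
    def test_mean_is_fold_average_and_best_defined(self, separable):
        X, conds = separable
        res = compare_models_cv(X, conds, folds=5, seed=0)
        for name, accs in res.fold_accuracies.items():
            assert len(accs) == 5
            assert res.mean_accuracy[name] == pytest.approx(np.mean(accs))
        assert res.best_model in res.fold_accuracies
        assert all(0 <= a <= 1 for accs in res.fold_accuracies.values() for a in accs)

    def test_separable_data_all_models_score_high(self, separable):
        X, conds = separable
        res = compare_models_cv(X, conds, folds=5, seed=1)
        assert all(m >= 0.7 for m in res.mean_accuracy.values())

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            make_model("mlp")


class TestHoldoutEvaluation:
    def test_roc_contract_and_perfect_scorer(self, separable):
        X, conds = separable
        clf, report = fit_final_and_evaluate(
            "xgboost", X, conds, X, conds, seed=0
        )  # leakage harness: holdout == training data
        assert report.roc_fpr[0] == 0 and report.roc_tpr[0] == 0
        assert report.roc_fpr[-1] == 1 and report.roc_tpr[-1] == 1
        assert report.accuracy >= 0.99 and report.auc == pytest.approx(1.0)

    def test_random_labels_near_chance(self):
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = np.abs(rng.normal(3, 1, size=(120, 5)))
            conds = list(rng.choice(["AP", "CRC"], size=120))
            tr, ho = np.arange(0, 90), np.arange(90, 120)
            _, report = fit_final_and_evaluate(
                "random_forest",
                X[tr], [conds[i] for i in tr], X[ho], [conds[i] for i in ho],
                seed=seed,
            )
            accs.append(report.accuracy)
        assert abs(np.mean(accs) - 0.5) <= 0.15

    def test_empty_holdout_rejected(self, separable):
        X, conds = separable
        with pytest.raises(ValueError, match="empty"):
            fit_final_and_evaluate("xgboost", X, conds, X[:0], [], seed=0)


class TestShapAttributions:
    @pytest.fixture(scope="class")
    def fitted_xgb(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(150, 5))
        y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
        clf = XGBClassifier(
            n_estimators=50, max_depth=3, learning_rate=0.2, random_state=0,
            n_jobs=1, base_score=0.5,
        )
        clf.fit(X, y)
        return clf, X

    def test_tree_exact_additivity_machine_precision(self, fitted_xgb):
        clf, X = fitted_xgb
        rep = shap_attributions(clf, X[:30], method="tree_exact")
        assert np.abs(rep.additivity_residuals).max() <= 1e-6

    def test_tree_exact_agrees_with_xgboost_builtin(self, fitted_xgb):
        """Independent cross-check against xgboost's own TreeSHAP."""
        import xgboost as xgb

        clf, X = fitted_xgb
        rep = shap_attributions(clf, X[:30], method="tree_exact")
        contribs = clf.get_booster().predict(
            xgb.DMatrix(X[:30]), pred_contribs=True
        )
        np.testing.assert_allclose(rep.values, contribs[:, :-1], atol=1e-4)
        assert rep.base_value == pytest.approx(float(contribs[0, -1]), abs=1e-4)

    def test_tree_exact_rejected_for_non_tree_model(self):
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression().fit(np.random.default_rng(0).normal(size=(20, 2)),
                                       [0, 1] * 10)
        with pytest.raises(TypeError, match="tree"):
            shap_attributions(clf, np.zeros((2, 2)), method="tree_exact")

    def test_single_feature_model_closed_form(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 1))
        y = (X[:, 0] > 0).astype(int)
        clf = XGBClassifier(n_estimators=20, max_depth=2, random_state=0,
                            n_jobs=1, base_score=0.5)
        clf.fit(X, y)
        background = X[:10]
        rep = shap_attributions(
            clf, X[:5], background=background, method="permutation_sampled",
            n_permutations=1, seed=0,
        )
        f = lambda Z: clf.predict(Z, output_margin=True)
        for i in range(5):
            expected = f(X[i : i + 1])[0] - f(background).mean()
            assert rep.values[i, 0] == pytest.approx(expected, abs=1e-6)

    def test_sampled_matches_exhaustive_enumeration(self, fitted_xgb):
        clf, X = fitted_xgb
        background = X[:8]
        f = lambda Z: clf.predict(Z, output_margin=True)
        rep = shap_attributions(
            clf, X[:4], background=background, method="permutation_sampled",
            n_permutations=2000, seed=3,
        )
        for i in range(4):
            exact = _exhaustive_shapley(f, X[i], background, p=5)
            np.testing.assert_allclose(rep.values[i], exact, atol=0.05)

    def test_sampled_additivity_telescopes(self, fitted_xgb):
        clf, X = fitted_xgb
        rep = shap_attributions(
            clf, X[:10], method="permutation_sampled", n_permutations=5, seed=0
        )
        assert np.abs(rep.additivity_residuals).max() <= 1e-6

    def test_symmetric_features_get_equal_attributions(self):
        # constructed model, exchangeable in features 0 and 1; identical
        # columns + identical model roles => identical Shapley values
        class SymModel:
            def decision_function(self, Z):
                return Z[:, 0] + Z[:, 1] + 0.5 * Z[:, 0] * Z[:, 1] - Z[:, 2]

        rng = np.random.default_rng(4)
        base = rng.normal(size=(30, 1))
        X = np.hstack([base, base, rng.normal(size=(30, 1))])
        model = SymModel()
        # the exact Shapley values are equal by the symmetry axiom
        for i in range(4):
            exact = _exhaustive_shapley(model.decision_function, X[i], X, p=3)
            assert exact[0] == pytest.approx(exact[1], abs=1e-9)
        # and the sampled estimator converges to them
        rep = shap_attributions(
            model, X[:4], background=X, method="permutation_sampled",
            n_permutations=4000, seed=1,
        )
        for i in range(4):
            exact = _exhaustive_shapley(model.decision_function, X[i], X, p=3)
            np.testing.assert_allclose(rep.values[i], exact, atol=0.05)


class TestExportPlotData:
    @pytest.fixture(scope="class")
    def report(self):
        values = np.array([[0.5, -0.1], [0.2, 0.3], [-0.4, 0.0]])
        return AttributionReport(
            feature_ids=["fA", "fB"],
            sample_ids=["s1", "s2", "s3"],
            base_value=0.1,
            values=values,
            model_output=0.1 + values.sum(axis=1),
            additivity_residuals=np.zeros(3),
            method="tree_exact",
        )

    def test_table_shapes(self, report):
        out = export_plot_data(report, np.zeros((3, 2)), ["AP", "CRC", "AP"])
        assert len(out["summary"]) == 2
        assert len(out["beeswarm"]) == 6
        assert len(out["force"]) == 6

    def test_top_ranked_matches_hand_mean_abs(self, report):
        out = export_plot_data(report, np.zeros((3, 2)), ["AP", "CRC", "AP"])
        hand = np.abs(report.values).mean(axis=0)
        assert out["summary"].iloc[0]["feature_id"] == report.feature_ids[int(np.argmax(hand))]

    def test_force_orders_ap_before_crc(self, report):
        out = export_plot_data(report, np.zeros((3, 2)), ["AP", "CRC", "AP"])
        conds = out["force"].drop_duplicates("sample_id")["condition"].tolist()
        assert conds == ["AP", "AP", "CRC"]
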