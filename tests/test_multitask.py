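"""Multitask forest: joint split score, collinearity filter, importance
ranking, subset selection, AUC machinery and the development split."""

import numpy as np
import pandas as pd
import pytest

import oracles
from radioshrink.cohort import CohortConfig, generate_feature_table
from radioshrink.multitask import (ForestHyperparams, ForestModel, auc,
                                   collinearity_filter, compare_auc_bootstrap,
                                   evaluate_auc, fit_multitask_forest,
                                   joint_importance, predict, predict_oob,
                                   random_grid_search, select_common_subset,
                                   split_development, split_score_multitask)


class TestSplitScore:
    """Hand computations on a 4-sample node, both tasks binary."""

    X = np.array([[0.0], [1.0], [2.0], [3.0]])

    def test_perfect_split_for_both_tasks(self):
        Y = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
        # parent gini 0.5 per task, children pure: decrease 0.5 per task
        assert split_score_multitask(self.X, Y, 0, 1.5) == pytest.approx(0.5)

    def test_split_informative_for_one_task_only(self):
        Y = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        # task 1 separates fully (decrease .5); task 2 children stay 50/50
        assert split_score_multitask(self.X, Y, 0, 1.5) == pytest.approx(0.25)

    def test_uninformative_split_scores_zero(self):
        Y = np.array([[0, 1], [1, 0], [0, 1], [1, 0]])
        assert split_score_multitask(self.X, Y, 0, 1.5) == pytest.approx(0.0)


class TestCollinearityFilter:
    def test_duplicate_dropped_by_mean_correlation_rule(self, rng):
        f3 = rng.normal(size=200)
        f2 = rng.normal(size=200)
        f1 = f2 + 0.3 * f3  # f1 == high r with f2, and more correlated to f3
        df = pd.DataFrame({"f1": f1, "f2": f2, "f3": f3})
        # force |r(f1,f2)| > 0.9
        assert abs(df.corr().loc["f1", "f2"]) > 0.9
        kept, log = collinearity_filter(df, 0.9)
        dropped = {e["dropped"] for e in log}
        assert dropped == {"f1"}
        assert list(kept.columns) == ["f2", "f3"]

    def test_uncorrelated_table_is_identity(self, rng):
        df = pd.DataFrame(rng.normal(size=(300, 6)),
                          columns=[f"g{i}" for i in range(6)])
        kept, log = collinearity_filter(df, 0.9)
        assert kept.shape == df.shape and not log

    def test_zero_variance_removed_first(self, rng):
        df = pd.DataFrame({"a": np.ones(50), "b": rng.normal(size=50),
                           "c": rng.normal(size=50)})
        kept, log = collinearity_filter(df)
        assert "a" not in kept.columns
        assert log[0]["reason"] == "zero_variance"

    def test_no_residual_high_correlation(self, rng):
        base = rng.normal(size=(150, 3))
        cols = {f"x{i}": base[:, i % 3] + rng.normal(0, 0.05, 150)
                for i in range(9)}
        kept, _ = collinearity_filter(pd.DataFrame(cols), 0.9)
        corr = kept.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.9


class TestForest:
    def test_single_task_reduction_is_exact(self):
        cfg = CohortConfig(n_patients=80, seed=21)
        X, y, _ = generate_feature_table(cfg)
        twin = pd.DataFrame({"a": y["cs"], "b": y["cs"]})
        hp = ForestHyperparams(n_trees=20)
        multi = fit_multitask_forest(X, twin, hp, seed=3)
        single = fit_multitask_forest(X, y[["cs"]], hp, seed=3)
        pm = predict(multi, X)
        ps = predict(single, X)
        assert np.array_equal(pm["a"].to_numpy(), ps["cs"].to_numpy())
        assert np.array_equal(pm["b"].to_numpy(), ps["cs"].to_numpy())

    def test_planted_signal_reaches_high_oob_auc(self):
        cfg = CohortConfig(n_patients=300, seed=22, n_shared_signal_features=5,
                           signal_effect_size=1.5)
        X, y, _ = generate_feature_table(cfg)
        m = fit_multitask_forest(X, y, ForestHyperparams(n_trees=100), seed=1)
        oob = predict_oob(m, X)
        assert auc(oob["cs"], y["cs"]) > 0.8
        assert auc(oob["pcr"], y["pcr"]) > 0.8

    def test_unseen_feature_rejected_by_name(self):
        cfg = CohortConfig(n_patients=50, seed=23)
        X, y, _ = generate_feature_table(cfg)
        m = fit_multitask_forest(X, y, ForestHyperparams(n_trees=5), seed=1)
        with pytest.raises(KeyError, match="absent"):
            predict(m, X.rename(columns={X.columns[0]: "mystery"}))

    def test_json_roundtrip_preserves_predictions(self):
        cfg = CohortConfig(n_patients=60, seed=24)
        X, y, _ = generate_feature_table(cfg)
        m = fit_multitask_forest(X, y, ForestHyperparams(n_trees=10), seed=2)
        m2 = ForestModel.from_json(m.to_json())
        assert predict(m, X).equals(predict(m2, X))

    def test_probabilities_bounded_and_deterministic(self):
        cfg = CohortConfig(n_patients=60, seed=25)
        X, y, _ = generate_feature_table(cfg)
        m = fit_multitask_forest(X, y, ForestHyperparams(n_trees=15), seed=4)
        p1, p2 = predict(m, X), predict(m, X)
        assert p1.equals(p2)
        assert ((p1 >= 0) & (p1 <= 1)).all().all()

    def test_deep_forest_overfits_training_set(self):
        cfg = CohortConfig(n_patients=100, seed=26)
        X, y, _ = generate_feature_table(cfg)
        hp = ForestHyperparams(n_trees=100, max_depth=20, min_leaf=1)
        m = fit_multitask_forest(X, y, hp, seed=5)
        p = predict(m, X)
        assert auc(p["cs"], y["cs"]) > 0.95


class TestImportance:
    def test_planted_features_outrank_noise(self):
        cfg = CohortConfig(n_patients=300, seed=27)
        X, y, truth = generate_feature_table(cfg)
        m = fit_multitask_forest(X, y, ForestHyperparams(n_trees=100), seed=6)
        ranking = joint_importance(m)
        top5 = set(ranking.index[:5])
        assert len(top5 & set(truth.signal_features)) >= 4

    def test_unused_feature_has_zero_importance(self):
        X = pd.DataFrame({"informative": [0, 0, 1, 1] * 25,
                          "constant": np.zeros(100)})
        y = pd.DataFrame({"cs": [0, 0, 1, 1] * 25, "pcr": [0, 0, 1, 1] * 25})
        m = fit_multitask_forest(X, y, ForestHyperparams(n_trees=20, mtry=2), seed=7)
        imp = joint_importance(m)
        assert imp["constant"] == 0.0
        assert imp["informative"] > 0.0


class TestSelection:
    def test_recovers_planted_subset(self):
        cfg = CohortConfig(n_patients=300, seed=28)
        X, y, truth = generate_feature_table(cfg)
        m = fit_multitask_forest(X, y, ForestHyperparams(n_trees=100), seed=8)
        sel = select_common_subset(X, y, joint_importance(m), k_grid=[4, 8],
                                   seed=8, hyperparams=ForestHyperparams(n_trees=15))
        assert len(set(sel.chosen_features) & set(truth.signal_features)) >= 4

    def test_single_k_degenerates_to_that_model(self):
        cfg = CohortConfig(n_patients=40, seed=29)
        X, y, _ = generate_feature_table(cfg)
        m = fit_multitask_forest(X, y, ForestHyperparams(n_trees=10), seed=9)
        ranking = joint_importance(m)
        sel = select_common_subset(X, y, ranking, k_grid=[len(ranking)], seed=9,
                                   hyperparams=ForestHyperparams(n_trees=5))
        assert sel.chosen_k == len(ranking)
        assert sel.chosen_features == list(ranking.index)

    def test_kgrid_clipped_with_warning(self):
        cfg = CohortConfig(n_patients=40, seed=30, n_noise_features=3,
                           n_shared_signal_features=2)
        X, y, _ = generate_feature_table(cfg)
        m = fit_multitask_forest(X, y, ForestHyperparams(n_trees=5), seed=1)
        with pytest.warns(UserWarning, match="clipped"):
            sel = select_common_subset(X, y, joint_importance(m),
                                       k_grid=[2, 50], seed=1,
                                       hyperparams=ForestHyperparams(n_trees=5))
        assert sel.loocv_curve["k"].max() <= 5


class TestGridSearch:
    def test_space_of_size_one_returned(self):
        cfg = CohortConfig(n_patients=50, seed=31)
        X, y, _ = generate_feature_table(cfg)
        out = random_grid_search({"n_trees": [10]}, X, y, n_draws=3, seed=0)
        assert out["best"] == {"n_trees": 10}

    def test_exhaustive_flag_visits_whole_space(self):
        cfg = CohortConfig(n_patients=50, seed=32)
        X, y, _ = generate_feature_table(cfg)
        space = {"n_trees": [5, 10], "max_depth": [2, 4]}
        out = random_grid_search(space, X, y, seed=0, exhaustive=True)
        assert len(out["trace"]) == 4

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            random_grid_search({}, None, None)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_pair_counting_on_random_inputs(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 1)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auc(scores, labels) == pytest.approx(
                oracles.auc_pair_counting(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_report_metrics_at_youden_threshold(self):
        scores = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        rep = evaluate_auc(scores, labels, n_boot=200, seed=0)
        assert rep.auc == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.ci_low <= rep.auc <= rep.ci_high


class TestCompareAuc:
    def test_identical_scores_p_near_one(self, rng):
        y = rng.integers(0, 2, 100)
        y[:5] = 1; y[5:10] = 0
        s = rng.random(100)
        out = compare_auc_bootstrap(s, s, y, n_boot=200, seed=0)
        assert out["p_value"] > 0.9

    def test_separating_vs_random_scores_significant(self, rng):
        y = np.repeat([0, 1], 100)
        good = y + rng.normal(0, 0.1, 200)
        bad = rng.random(200)
        out = compare_auc_bootstrap(good, bad, y, n_boot=500, seed=1)
        assert out["p_value"] < 0.01

    def test_invariant_to_monotone_transform(self, rng):
        y = np.repeat([0, 1], 50)
        s = rng.random(100)
        a = compare_auc_bootstrap(s, s * 0 + 0.5, y, n_boot=300, seed=2)
        b = compare_auc_bootstrap(np.exp(3 * s), s * 0 + 0.5, y, n_boot=300, seed=2)
        assert a["p_value"] == b["p_value"]


class TestDevelopmentSplit:
    def test_255_patients_split_168_87(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(255, 3)))
        y = pd.DataFrame({"cs": rng.integers(0, 2, 255),
                          "pcr": rng.integers(0, 2, 255)})
        train, val = split_development(X, y, frac=0.66, seed=1)
        assert len(train) == 168 and len(val) == 87
        assert len(set(train) & set(val)) == 0
        assert len(set(train) | set(val)) == 255

    def test_full_fraction_rejected(self):
        X = pd.DataFrame(np.zeros((10, 2)))
        y = pd.DataFrame({"cs": [0, 1] * 5, "pcr": [0, 1] * 5})
        with pytest.raises(ValueError):
            split_development(X, y, frac=1.0)

    def test_stratum_prevalence_preserved_within_one(self):
        rng = np.random.default_rng(3)
        y = pd.DataFrame({"cs": rng.integers(0, 2, 200),
                          "pcr": rng.integers(0, 2, 200)})
        X = pd.DataFrame(rng.normal(size=(200, 2)))
        train, _ = split_development(X, y, frac=0.66, seed=2)
        for key, grp in y.groupby(["cs", "pcr"]):
            expect = 0.66 * len(grp)
            got = len(set(train) & set(X.index.get_indexer(grp.index)))
            assert abs(got - expect) <= 1
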