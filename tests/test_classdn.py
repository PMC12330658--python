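"""ClassDn: resampling ensembles, scoring, thresholding, performance."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from tadard import (SchemaError, SimulatedCohortConfig, classify_at_threshold,
                    estimate_performance, generate_labeled_table,
                    performance_curve, score_variants, train_classdn)
from tadard.classdn import load_model, save_model


class TestTraining:
    @pytest.mark.parametrize("algorithm", ["rusboost", "underbagging"])
    def test_separable_data_high_auc(self, train_test_tables, algorithm):
        train, test = train_test_tables
        model = train_classdn(train, algorithm=algorithm, rng_seed=7)
        scores = score_variants(model, test)
        assert roc_auc_score(test["label"], scores) > 0.95

    @pytest.mark.parametrize("algorithm", ["rusboost", "underbagging"])
    def test_permuted_labels_no_signal(self, algorithm):
        # class-balanced cohort so the held-out AUC null band is tight
        config = SimulatedCohortConfig(n_genes=200, n_variants_total=4000,
                                       risk_gene_fraction=1.0,
                                       denovo_fraction_risk=0.5,
                                       denovo_fraction_nonrisk=0.026,
                                       rng_seed=5)
        table = generate_labeled_table(config)
        rng = np.random.default_rng(11)
        table = table.assign(label=rng.permutation(table["label"].to_numpy()))
        train, test = table.iloc[:2600], table.iloc[2600:]
        model = train_classdn(train, algorithm=algorithm, rng_seed=3)
        auc = roc_auc_score(test["label"], score_variants(model, test))
        assert 0.45 < auc < 0.55

    def test_single_class_unfittable(self, labeled_cohort):
        degenerate = labeled_cohort.assign(label=0)
        with pytest.raises(ValueError, match="single inheritance class"):
            train_classdn(degenerate)

    def test_missing_covariate_column_named(self, labeled_cohort):
        broken = labeled_cohort.drop(columns=["CCR"])
        with pytest.raises(SchemaError, match="CCR"):
            train_classdn(broken)

    def test_rows_with_missing_values_dropped(self, labeled_cohort):
        table = labeled_cohort.copy()
        table.loc[table.index[:5], "LOEUF"] = np.nan
        model = train_classdn(table, rng_seed=1)
        assert model.n_dropped_rows == 5

    def test_seed_determinism(self, train_test_tables):
        train, test = train_test_tables
        s1 = score_variants(train_classdn(train, rng_seed=9), test)
        s2 = score_variants(train_classdn(train, rng_seed=9), test)
        np.testing.assert_array_equal(s1, s2)

    @pytest.mark.parametrize("algorithm", ["rusboost", "underbagging"])
    def test_every_subsample_is_class_balanced(self, train_test_tables,
                                               algorithm):
        train, _ = train_test_tables
        model = train_classdn(train, algorithm=algorithm, rng_seed=2,
                              hyperparams={"n_estimators": 25})
        counts = model.estimator.subsample_class_counts_
        assert counts and all(n0 == n1 for n0, n1 in counts)


class TestScoring:
    def test_scores_in_unit_interval(self, fitted_rusboost):
        _, _, scores = fitted_rusboost
        assert np.all((scores >= 0) & (scores <= 1))

    def test_empty_table_empty_scores(self, fitted_rusboost):
        model, test, _ = fitted_rusboost
        assert score_variants(model, test.iloc[:0]).size == 0

    def test_duplicated_row_gets_identical_score(self, fitted_rusboost):
        model, test, _ = fitted_rusboost
        dup = pd.concat([test.iloc[[3]], test.iloc[[3]]])
        s = score_variants(model, dup)
        assert s[0] == s[1]

    def test_denovo_scores_stochastically_larger(self, fitted_rusboost):
        _, test, scores = fitted_rusboost
        labels = test["label"].to_numpy()
        res = mannwhitneyu(scores[labels == 1], scores[labels == 0],
                           alternative="greater")
        assert res.pvalue < 1e-6

    def test_missing_column_reported(self, fitted_rusboost):
        model, test, _ = fitted_rusboost
        with pytest.raises(SchemaError, match="AF"):
            score_variants(model, test.drop(columns=["AF"]))


class TestThresholding:
    def test_strict_exceedance(self):
        # a score exactly at the threshold is "likely inherited"
        np.testing.assert_array_equal(
            classify_at_threshold([0.7, 0.71, 0.0], 0.7), [0, 1, 0])

    def test_threshold_one_classifies_nothing(self):
        assert classify_at_threshold(np.linspace(0, 1, 11), 1.0).sum() == 0

    def test_performance_hand_example(self):
        w1, w2 = estimate_performance([1, 1, 0, 0], [1, 0, 0, 1])
        assert (w1, w2) == (0.5, 0.5)

    def test_perfect_predictions(self):
        assert estimate_performance([1, 0], [1, 0]) == (1.0, 1.0)

    def test_all_predicted_inherited(self):
        assert estimate_performance([1, 0], [0, 0]) == (0.0, 1.0)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            estimate_performance([1, 1], [1, 0])


class TestPerformanceCurve:
    def test_matches_pointwise_composition(self, fitted_rusboost):
        _, test, scores = fitted_rusboost
        grid = np.linspace(0, 1, 21)
        curve = performance_curve(test["label"], scores, grid)
        for _, row in curve.iloc[::5].iterrows():
            w1, w2 = estimate_performance(
                test["label"], classify_at_threshold(scores, row["threshold"]))
            assert (row["sensitivity"], row["specificity"]) == (w1, w2)

    def test_monotone_tradeoff(self, fitted_rusboost):
        _, test, scores = fitted_rusboost
        curve = performance_curve(test["label"], scores, np.linspace(0, 1, 51))
        assert (np.diff(curve["sensitivity"]) <= 1e-12).all()
        assert (np.diff(curve["specificity"]) >= -1e-12).all()

    def test_degenerate_grid_points(self, fitted_rusboost):
        _, test, scores = fitted_rusboost
        curve = performance_curve(test["label"], np.clip(scores, 1e-6, 1),
                                  [0.0, 1.0])
        assert curve.loc[0, "sensitivity"] == 1.0
        assert curve.loc[1, "sensitivity"] == 0.0
        assert curve.loc[1, "specificity"] == 1.0


def test_model_round_trip(tmp_path, fitted_rusboost):
    model, test, scores = fitted_rusboost
    path = tmp_path / "model.pkl"
    save_model(model, path)
    reloaded = load_model(path)
    np.testing.assert_array_equal(score_variants(reloaded, test), scores)
    assert reloaded.feature_order == model.feature_order
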