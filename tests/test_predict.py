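"""The discriminant prediction rule and its evaluation machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bmitrans as bt
from bmitrans.model import ModelParams, probability_matrix
from bmitrans.predict import crude_all_normal_report, predict_cohort


class TestPredictCategory:
    def test_reference_point_predicts_overweight(self, truth_params):
        pred = bt.predict_category(truth_params, (1, 1, 8, 130, 20))
        assert pred.category == 3 and not pred.tie

    def test_four_way_tie_breaks_low_with_flag(self):
        pred = bt.predict_category(ModelParams.zeros(), (1, 1, 8, 130, 20))
        assert pred.category == 1 and pred.tie

    @given(
        beta=st.lists(st.floats(-2, 2), min_size=18, max_size=18),
        x=st.tuples(
            st.integers(0, 1), st.integers(0, 1), st.integers(6, 11),
            st.floats(100, 180), st.floats(10, 35),
        ),
    )
    def test_linear_rule_equals_probability_rule(self, beta, x):
        """argmax over linear predictors = argmax over probabilities."""
        params = ModelParams.from_flat(beta)
        pred = bt.predict_category(params, x)
        assert pred.category == int(np.argmax(bt.category_probs(params, x))) + 1


class TestClassificationReport:
    def test_perfect_prediction(self):
        obs = [1, 2, 3, 4, 2, 3]
        rep = bt.classification_report(obs, obs)
        assert rep.overall_accuracy == 1.0
        assert np.allclose(rep.sensitivity, 1.0)
        assert np.allclose(rep.specificity, 1.0)

    def test_counts_conserved(self, truth_params, cohort_small):
        predicted, _ = predict_cohort(truth_params, cohort_small)
        rep = bt.classification_report(cohort_small["category18"].to_numpy(int), predicted)
        assert rep.confusion.sum() == len(cohort_small)
        assert np.array_equal(
            rep.confusion.sum(axis=1),
            np.array([(cohort_small["category18"] == c).sum() for c in (1, 2, 3, 4)]),
        )

    def test_crude_all_normal_on_published_margins(self, ref_tables):
        """Predicting 'normal' for everyone on the published cohort gets
        50,600 / 88,980 = 57% right (to the printed rounding)."""
        table = ref_tables["overall"]
        observed = np.repeat([1, 2, 3, 4], table.col_totals.astype(int))
        frame = pd.DataFrame({"id": np.arange(len(observed)), "category18": pd.array(observed, dtype="Int64")})
        rep = crude_all_normal_report(frame)
        assert rep.overall_accuracy == pytest.approx(50600 / 88980)
        assert round(100 * rep.overall_accuracy) == 57

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            bt.classification_report([1, 2], [1])

    def test_independent_predictions_accuracy(self):
        """Label-independent predictions score ~ sum of share products."""
        rng = np.random.default_rng(4)
        obs = rng.choice([1, 2, 3, 4], p=[0.1, 0.5, 0.2, 0.2], size=40000)
        pred = rng.choice([1, 2, 3, 4], p=[0.25, 0.25, 0.25, 0.25], size=40000)
        rep = bt.classification_report(obs, pred)
        expected = (np.array([0.1, 0.5, 0.2, 0.2]) * 0.25).sum()
        assert rep.overall_accuracy == pytest.approx(expected, abs=0.01)


class TestCrossValidate:
    def test_deterministic(self, cohort_small):
        a = bt.cross_validate(cohort_small, k=5, repeats=2, seed=9)
        b = bt.cross_validate(cohort_small, k=5, repeats=2, seed=9)
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_single_repeat_has_zero_sd(self, cohort_small):
        cv = bt.cross_validate(cohort_small, k=5, repeats=1, seed=9)
        assert cv.accuracy_sd == 0.0

    def test_cv_accuracy_near_training_accuracy(self, cohort_medium):
        """An 18-parameter model barely overfits 20,000 records: CV accuracy
        within 2 percentage points of full-data training accuracy."""
        cv = bt.cross_validate(cohort_medium, k=5, repeats=2, seed=9)
        fit = bt.fit_smle(cohort_medium)
        predicted, _ = predict_cohort(fit.params, cohort_medium)
        train_acc = bt.classification_report(
            cohort_medium["category18"].to_numpy(int), predicted
        ).overall_accuracy
        assert abs(cv.accuracy_mean - train_acc) < 0.02

    def test_model_beats_crude_baseline(self, cohort_medium):
        """On data simulated from the transition model the argmax rule beats
        the all-normal crude baseline."""
        fit = bt.fit_smle(cohort_medium)
        predicted, _ = predict_cohort(fit.params, cohort_medium)
        y = cohort_medium["category18"].to_numpy(int)
        model_acc = bt.classification_report(y, predicted).overall_accuracy
        crude_acc = crude_all_normal_report(cohort_medium).overall_accuracy
        assert model_acc >= crude_acc

    def test_small_stratum_is_an_error(self, cohort_small):
        rare = cohort_small.copy()
        y = rare["category18"].to_numpy(int)
        y[y == 1] = 2
        y[0] = 1  # a single member of category 1
        rare["category18"] = pd.array(y, dtype="Int64")
        with pytest.raises(ValueError, match="fewer than"):
            bt.cross_validate(rare, k=5, repeats=1, seed=0)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = bt.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_constant_scores(self):
        _, auc = bt.roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == 0.5

    def test_matches_exhaustive_pair_counting(self):
        """Mann-Whitney AUC equals brute-force pair counting (with tie
        half-credit) to 1e-12 on a tied 200-point instance."""
        rng = np.random.default_rng(21)
        labels = (rng.random(200) < 0.4).astype(int)
        scores = np.round(rng.normal(0, 1, 200), 1)  # heavy ties
        _, auc = bt.roc_auc(labels, scores)
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(22)
        labels = (rng.random(300) < 0.3).astype(int)
        scores = rng.normal(0, 1, 300)
        _, auc_raw = bt.roc_auc(labels, scores)
        _, auc_exp = bt.roc_auc(labels, np.exp(2.0 * scores) + 5.0)
        assert auc_raw == pytest.approx(auc_exp, abs=1e-12)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="both classes"):
            bt.roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_submodel_aucs_informative(self, truth_params, cohort_medium):
        """Each j-vs-normal submodel discriminates clearly better than chance
        on data simulated from the model."""
        for j in (1, 3, 4):
            _, auc = bt.submodel_roc(truth_params, cohort_medium, j)
            assert auc > 0.7


class TestExpectedTransitionTable:
    def test_null_model_splits_rows_equally(self, cohort_small):
        table = bt.expected_transition_table(ModelParams.zeros(), cohort_small)
        pct = table.row_percentages(rounded=False)
        assert np.allclose(pct, 25.0)

    def test_rows_sum_to_observed_baseline_totals(self, truth_params, cohort_small):
        table = bt.expected_transition_table(truth_params, cohort_small)
        observed = np.array([(cohort_small["category13"] == c).sum() for c in (1, 2, 3, 4)])
        assert np.allclose(table.row_totals, observed)

    def test_expected_close_to_observed_under_truth(self, truth_params, cohort_medium):
        """Expected cells track observed cells within 3 multinomial SDs for
        nearly all cells when the model generated the data."""
        expected = bt.expected_transition_table(truth_params, cohort_medium).counts
        [observed] = bt.crosstab(cohort_medium)
        probs = probability_matrix(truth_params, cohort_medium)
        cat13 = cohort_medium["category13"].to_numpy(int)
        within = 0
        for a in range(4):
            p = probs[cat13 == a + 1]
            sd = np.sqrt((p * (1 - p)).sum(axis=0))
            within += (np.abs(observed.counts[a] - expected[a]) <= 3 * np.maximum(sd, 1.0)).sum()
        assert within >= 14
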