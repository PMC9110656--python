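"""Tests of LOSO cross-validation, weighted metrics and agreement stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import precision_score, recall_score

from aratscore import (
    ConfusionMatrix,
    agreement_stats,
    make_loso_folds,
    run_cross_validation,
    total_scores,
    weighted_metrics,
)
from aratscore.evaluation import confusion_from_predictions


class TestLosoFolds:
    def test_one_fold_per_subject(self, small_table):
        plan = make_loso_folds(small_table)
        subjects = sorted(small_table["subject"].unique())
        assert len(plan) == len(subjects)
        assert sorted(test for _, test in plan.folds) == subjects

    def test_test_subject_never_in_training(self, small_table):
        for train, test in make_loso_folds(small_table).folds:
            assert test not in train

    def test_every_row_in_exactly_one_test_fold(self, small_table):
        counts = pd.Series(0, index=small_table.index)
        for _, test in make_loso_folds(small_table).folds:
            counts[small_table["subject"] == test] += 1
        assert (counts == 1).all()

    def test_single_subject_rejected(self, small_table):
        one = small_table[small_table["subject"] == small_table["subject"].iloc[0]]
        with pytest.raises(ValueError):
            make_loso_folds(one)


class TestWeightedMetrics:
    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(np.diag([5, 7, 3]), labels=[0, 1, 2])
        assert weighted_metrics(cm) == (1.0, 1.0, 1.0)

    def test_hand_computed_two_class_matrix(self):
        """[[2,0],[1,3]]: weighted recall 5/6, weighted precision 8/9."""
        cm = ConfusionMatrix(np.array([[2, 0], [1, 3]]), labels=[0, 1])
        acc, prec, rec = weighted_metrics(cm)
        assert rec == pytest.approx(5 / 6)
        assert acc == pytest.approx(5 / 6)
        assert prec == pytest.approx(8 / 9)

    def test_matches_sklearn_weighted_averages(self, rng):
        true = rng.integers(0, 4, 200)
        pred = rng.integers(0, 4, 200)
        cm = confusion_from_predictions(true, pred)
        acc, prec, rec = weighted_metrics(cm)
        assert prec == pytest.approx(
            precision_score(true, pred, average="weighted", zero_division=0)
        )
        assert rec == pytest.approx(
            recall_score(true, pred, average="weighted", zero_division=0)
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_weighted_recall_equals_accuracy(self, seed):
        """Support weighting makes weighted recall identical to overall
        accuracy for any non-empty count matrix."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, (4, 4))
        if counts.sum() == 0:
            counts[0, 0] = 1
        cm = ConfusionMatrix(counts, labels=[0, 1, 2, 3])
        acc, _, rec = weighted_metrics(cm)
        assert rec == pytest.approx(acc, abs=1e-12)
        assert acc == pytest.approx(np.trace(counts) / counts.sum())

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            weighted_metrics(ConfusionMatrix(np.zeros((2, 2), dtype=int), labels=[0, 1]))

    def test_row_sums_equal_supports(self, rng):
        counts = rng.integers(0, 10, (3, 3))
        cm = ConfusionMatrix(counts, labels=[1, 2, 3])
        np.testing.assert_array_equal(cm.supports, counts.sum(axis=1))
        norm = cm.normalized()
        nz = cm.supports > 0
        np.testing.assert_allclose(norm[nz].sum(axis=1), 1.0)


def _prediction_frame(groups):
    """groups: list of (subject, session, arm, task_scores, predicted)."""
    rows = []
    for subj, ses, arm, scores, preds in groups:
        for i, (s, p) in enumerate(zip(scores, preds), start=1):
            rows.append(
                {
                    "subject": subj,
                    "session": ses,
                    "arm": arm,
                    "task": i,
                    "score": s,
                    "predicted": p,
                }
            )
    df = pd.DataFrame(rows)
    df["predicted"] = df["predicted"].astype("Int64")
    return df


class TestTotalScores:
    def test_perfect_scores_sum_to_57(self):
        df = _prediction_frame([("S01", 1, "less_affected", [3] * 19, [3] * 19)])
        totals = total_scores(df)
        assert totals.loc[0, "clinical_total"] == 57
        assert totals.loc[0, "estimated_total"] == 57

    def test_all_zero(self):
        df = _prediction_frame([("S01", 1, "more_affected", [0] * 19, [0] * 19)])
        totals = total_scores(df)
        assert totals.loc[0, "clinical_total"] == 0

    def test_mixed_hand_computed_total(self):
        scores = [3] * 10 + [2] * 5 + [1] * 4
        df = _prediction_frame([("S01", 1, "more_affected", scores, scores)])
        totals = total_scores(df)
        assert totals.loc[0, "clinical_total"] == 44 == sum(scores)

    def test_unpredicted_rows_count_as_zero(self):
        preds = [3] * 18 + [pd.NA]
        df = _prediction_frame([("S01", 1, "more_affected", [3] * 19, preds)])
        totals = total_scores(df)
        assert totals.loc[0, "estimated_total"] == 54

    def test_wrong_group_size_rejected(self):
        df = _prediction_frame([("S01", 1, "more_affected", [3] * 18, [3] * 18)])
        with pytest.raises(ValueError, match="19"):
            total_scores(df)


class TestAgreementStats:
    def test_identity_is_perfect(self):
        totals = np.array([10.0, 25.0, 40.0, 57.0])
        stats = agreement_stats(totals, totals)
        assert stats["r_squared"] == pytest.approx(1.0)
        for key in ("mean_error", "mean_absolute_error", "rmse", "max_absolute_error"):
            assert stats[key] == 0.0
        assert stats["slope"] == pytest.approx(1.0)

    def test_relative_error_of_printed_rmse(self):
        """An RMSE of 4.7 points out of a 57-point maximum is 8.2%."""
        assert round(100 * 4.7 / 57, 1) == 8.2

    def test_hand_computed_error_block(self):
        clinical = np.array([10.0, 20.0, 30.0])
        estimated = np.array([12.0, 19.0, 33.0])
        stats = agreement_stats(clinical, estimated)
        assert stats["mean_absolute_error"] == pytest.approx(2.0)
        # errors are +2, -1, +3 -> mean (2 - 1 + 3) / 3 = 4/3
        assert stats["mean_error"] == pytest.approx(4 / 3)
        assert stats["max_absolute_error"] == pytest.approx(3.0)
        assert stats["rmse"] == pytest.approx(np.sqrt((4 + 1 + 9) / 3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            agreement_stats(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0]))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            agreement_stats(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestRunCrossValidation:
    def test_every_row_predicted(self, small_table):
        out = run_cross_validation(small_table)
        assert out["predicted"].notna().all()
        assert out["predicted"].isin([0, 1, 2, 3]).all()

    def test_deterministic_given_seed(self, small_table):
        a = run_cross_validation(small_table)
        b = run_cross_validation(small_table)
        pd.testing.assert_series_equal(a["predicted"], b["predicted"])

    def test_row_order_invariance(self, small_table):
        """Shuffling row order (including other subjects' test rows) does
        not change any prediction: no leakage through ordering."""
        base = run_cross_validation(small_table)
        shuffled = small_table.sample(frac=1.0, random_state=99)
        out = run_cross_validation(shuffled)
        merged = base.merge(
            out,
            on=["subject", "session", "arm", "task"],
            suffixes=("_a", "_b"),
        )
        assert (merged["predicted_a"] == merged["predicted_b"]).all()
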