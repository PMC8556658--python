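"""Metrics arithmetic and subject-independent cross-validation plumbing."""

import numpy as np
import pytest

from sleepgcn.evaluation import (
    ConfusionMatrix,
    compute_metrics,
    cross_validate,
    subject_kfold,
)
from sleepgcn.features import Standardizer
from sleepgcn.model import ModelConfig
from sleepgcn.synthetic import SyntheticSpec, cohort_windows, generate_cohort


class TestComputeMetrics:
    def test_perfect_diagonal(self):
        m = compute_metrics(ConfusionMatrix(np.diag([3, 4, 5, 6, 7])))
        assert m["accuracy"] == 1.0
        assert m["macro_f1"] == 1.0
        assert m["kappa"] == 1.0

    def test_chance_level_two_class(self):
        m = compute_metrics(ConfusionMatrix(np.array([[1, 1], [1, 1]]), ("a", "b")))
        assert m["accuracy"] == 0.5
        assert m["kappa"] == 0.0

    def test_hand_computed_two_class_instance(self):
        m = compute_metrics(ConfusionMatrix(np.array([[4, 1], [2, 3]]), ("a", "b")))
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["kappa"] == pytest.approx(0.4)
        assert m["per_class_f1"][0] == pytest.approx(8 / 11)
        assert m["per_class_f1"][1] == pytest.approx(6 / 9)

    def test_degenerate_single_cell(self):
        with pytest.warns(UserWarning, match="degenerate"):
            m = compute_metrics(ConfusionMatrix(np.array([[7]]), ("a",)))
        assert m["kappa"] == 1.0

    def test_all_mass_off_diagonal_gives_nonpositive_kappa(self):
        m = compute_metrics(ConfusionMatrix(np.array([[0, 5], [0, 0]]), ("a", "b")))
        assert m["accuracy"] == 0.0
        assert m["kappa"] <= 0.0

    def test_macro_f1_ignores_classes_absent_from_truth(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 0] = 8
        counts[1, 1] = 2
        counts[1, 0] = 2
        m = compute_metrics(ConfusionMatrix(counts))
        f1_0 = 2 * 8 / (8 + 10)  # true marginal 8, predicted marginal 10
        f1_1 = 2 * 2 / (4 + 2)
        assert m["macro_f1"] == pytest.approx((f1_0 + f1_1) / 2)

    def test_agrees_with_sklearn_on_random_labels(self, rng):
        from sklearn.metrics import cohen_kappa_score, f1_score

        y_true = rng.integers(0, 5, size=300)
        y_pred = rng.integers(0, 5, size=300)
        m = compute_metrics(ConfusionMatrix.from_labels(y_true, y_pred))
        assert m["kappa"] == pytest.approx(cohen_kappa_score(y_true, y_pred), abs=1e-12)
        assert m["macro_f1"] == pytest.approx(
            f1_score(y_true, y_pred, average="macro"), abs=1e-12
        )
        assert m["accuracy"] == pytest.approx((y_true == y_pred).mean(), abs=1e-12)


class TestSubjectKfold:
    def test_ten_subjects_ten_folds_is_loso(self):
        subjects = [f"S{i}" for i in range(10)]
        plan = subject_kfold(subjects, 10, seed=1)
        sizes = [len(plan.fold_subjects(f)) for f in range(10)]
        assert sizes == [1] * 10

    def test_same_seed_identical_plan(self):
        subjects = [f"S{i}" for i in range(9)]
        assert subject_kfold(subjects, 4, seed=3).assignments == subject_kfold(
            subjects, 4, seed=3
        ).assignments

    def test_seven_subjects_three_folds_sizes(self):
        plan = subject_kfold([f"S{i}" for i in range(7)], 3, seed=0)
        sizes = sorted(len(plan.fold_subjects(f)) for f in range(3))
        assert sizes == [2, 2, 3]

    def test_more_folds_than_subjects_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            subject_kfold(["a", "b"], 3)

    def test_every_subject_in_exactly_one_fold(self):
        subjects = [f"S{i}" for i in range(11)]
        plan = subject_kfold(subjects, 4, seed=9)
        seen = [s for f in range(4) for s in plan.fold_subjects(f)]
        assert sorted(seen) == sorted(subjects)


class _OracleModel:
    """Stand-in predictor that copies the true labels (plumbing check)."""

    captured_train: list = []

    def __init__(self, config, montage, n_domains=1):
        pass

    def fit(self, windows, verbose=False):
        _OracleModel.captured_train.append(windows)
        return self

    def predict(self, windows, batch_size=256):
        labels = np.array([w.label for w in windows])
        return {"labels": labels, "proba": np.eye(5)[labels]}


@pytest.fixture
def oracle_cv(monkeypatch):
    monkeypatch.setattr("sleepgcn.evaluation.build_model", _OracleModel)
    _OracleModel.captured_train = []
    return _OracleModel


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        spec = SyntheticSpec(n_subjects=5, epochs_per_subject=40, n_channels=6, seed=2)
        recordings = generate_cohort(spec)
        return recordings, cohort_windows(recordings, d=1)

    def test_oracle_predictor_scores_one_everywhere(self, small_cohort, oracle_cv):
        recordings, windows = small_cohort
        report = cross_validate(windows, recordings[0].montage, ModelConfig(seed=0))
        assert all(m["accuracy"] == 1.0 for m in report.fold_metrics)
        assert report.pooled_metrics["accuracy"] == 1.0
        assert report.pooled_metrics["kappa"] == 1.0

    def test_new_fold_seed_changes_assignment_not_oracle_metrics(self, small_cohort, oracle_cv):
        recordings, windows = small_cohort
        r1 = cross_validate(windows, recordings[0].montage, ModelConfig(seed=0), n_folds=2, fold_seed=1)
        r2 = cross_validate(windows, recordings[0].montage, ModelConfig(seed=0), n_folds=2, fold_seed=2)
        assert r1.pooled_metrics["accuracy"] == r2.pooled_metrics["accuracy"] == 1.0

    def test_pooled_matrix_is_sum_of_fold_matrices(self, small_cohort, oracle_cv):
        recordings, windows = small_cohort
        report = cross_validate(windows, recordings[0].montage, ModelConfig(seed=0), n_folds=3)
        assert np.array_equal(
            report.pooled_matrix.counts,
            sum(cm.counts for cm in report.fold_matrices),
        )

    def test_no_test_subject_leaks_into_training_standardisation(self, small_cohort, oracle_cv):
        recordings, windows = small_cohort
        # corrupt one subject's features by a huge factor; if that subject is
        # held out, the training-fold standardised values must be unchanged
        target = "S04"
        scaled = [
            type(w)(
                w.features * (100.0 if w.subject_id == target else 1.0),
                w.label, w.subject_id, w.center_index,
            )
            for w in windows
        ]
        clean_train = [w for w in windows if w.subject_id != target]
        scaler = Standardizer().fit(clean_train)
        expected = scaler.transform(clean_train)

        _OracleModel.captured_train = []
        cross_validate(scaled, recordings[0].montage, ModelConfig(seed=0), n_folds=5, fold_seed=0)
        plan = subject_kfold([r.subject_id for r in recordings], 5, seed=0)
        fold_of_target = plan.assignments[target]
        captured = _OracleModel.captured_train[fold_of_target]
        got = np.concatenate([w.features for w in captured], axis=2)
        want = np.concatenate([w.features for w in expected], axis=2)
        assert np.allclose(got, want, atol=1e-10)
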