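"""Metrics and subject-independent cross-validation.

Staging performance is summarised by overall accuracy, per-class and macro
F1, Cohen's kappa and the confusion matrix.  Cross-validation is
*subject-independent*: folds partition subjects, never windows, so no
recording contributes to both training and evaluation — including the
feature-standardisation statistics, which are fit on training subjects only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import STAGE_NAMES, ContextWindow, Standardizer, windows_to_array
from .model import ModelConfig, SleepGCN, build_model

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Integer count matrix; rows are true stages, columns predicted."""

    counts: np.ndarray
    stage_names: tuple[str, ...] = STAGE_NAMES

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix entries must be nonnegative")

    @classmethod
    def from_labels(cls, y_true, y_pred, n_classes: int = len(STAGE_NAMES)):
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        counts = np.zeros((n_classes, n_classes), dtype=int)
        np.add.at(counts, (y_true, y_pred), 1)
        return cls(counts, STAGE_NAMES[:n_classes] if n_classes <= 5 else tuple(map(str, range(n_classes))))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts, self.stage_names)


def compute_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, per-class F1, macro F1 and Cohen's kappa from a count matrix.

    Macro F1 averages only over classes present in the truth; a class with
    zero precision+recall gets F1 = 0.  Kappa uses the marginal-product
    chance agreement; the fully degenerate single-cell case is defined as 1
    for perfect agreement and 0 otherwise.
    """
    counts = np.asarray(cm.counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    accuracy = np.trace(counts) / total
    true_marg = counts.sum(axis=1)
    pred_marg = counts.sum(axis=0)
    per_class_f1 = np.zeros(len(counts))
    for r in range(len(counts)):
        denom = true_marg[r] + pred_marg[r]
        per_class_f1[r] = 2.0 * counts[r, r] / denom if denom > 0 else 0.0
    present = true_marg > 0
    macro_f1 = float(per_class_f1[present].mean()) if present.any() else 0.0
    p_o = accuracy
    p_e = float((true_marg * pred_marg).sum() / total**2)
    if p_e >= 1.0:
        warnings.warn("degenerate chance agreement p_e = 1; kappa set by convention")
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return {
        "accuracy": float(accuracy),
        "macro_f1": macro_f1,
        "per_class_f1": per_class_f1,
        "kappa": float(kappa),
    }


@dataclass
class FoldPlan:
    """Mapping subject -> fold; every subject sits in exactly one fold."""

    assignments: dict[str, int]
    n_folds: int

    def fold_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignments.items() if f == fold)


def subject_kfold(subject_ids, n_folds: int, seed: int = 0) -> FoldPlan:
    """Shuffle subjects with ``seed`` and deal them round-robin into folds."""
    subjects = sorted(set(subject_ids))
    if n_folds > len(subjects):
        raise ValueError(f"n_folds={n_folds} exceeds the {len(subjects)} subjects")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    order = np.random.default_rng(seed).permutation(len(subjects))
    assignments = {subjects[j]: i % n_folds for i, j in enumerate(order)}
    return FoldPlan(assignments, n_folds)


@dataclass
class CVReport:
    """Per-fold and pooled cross-validation results."""

    fold_metrics: list[dict]
    fold_matrices: list[ConfusionMatrix]
    pooled_matrix: ConfusionMatrix
    pooled_metrics: dict = field(init=False)

    def __post_init__(self):
        self.pooled_metrics = compute_metrics(self.pooled_matrix)

    def summary(self) -> str:
        lines = ["fold\taccuracy\tmacro_f1\tkappa"]
        for i, m in enumerate(self.fold_metrics):
            lines.append(f"{i}\t{m['accuracy']:.4f}\t{m['macro_f1']:.4f}\t{m['kappa']:.4f}")
        accs = [m["accuracy"] for m in self.fold_metrics]
        p = self.pooled_metrics
        lines.append(
            f"mean\t{np.mean(accs):.4f} ± {np.std(accs):.4f}"
        )
        lines.append(f"pooled\t{p['accuracy']:.4f}\t{p['macro_f1']:.4f}\t{p['kappa']:.4f}")
        return "\n".join(lines)


def cross_validate(
    windows: list[ContextWindow],
    montage,
    config: ModelConfig,
    n_folds: int | None = None,
    fold_seed: int = 0,
    verbose: bool = False,
) -> CVReport:
    """Subject-independent k-fold CV (default: leave-one-subject-out).

    Per fold: standardisation statistics and the model are fit on training
    subjects only, then evaluated on the held-out subjects' windows.
    """
    _, _, subj_all = windows_to_array(windows)
    subjects = sorted(set(subj_all.tolist()))
    if n_folds is None:
        n_folds = len(subjects)
    plan = subject_kfold(subjects, n_folds, seed=fold_seed)
    fold_metrics, fold_matrices = [], []
    for fold in range(plan.n_folds):
        test_subjects = set(plan.fold_subjects(fold))
        train_w = [w for w in windows if w.subject_id not in test_subjects]
        test_w = [w for w in windows if w.subject_id in test_subjects]
        scaler = Standardizer().fit(train_w)
        train_std = scaler.transform(train_w)
        test_std = scaler.transform(test_w)
        if len({w.label for w in train_std}) < len(STAGE_NAMES):
            logger.warning("fold %d training set is missing classes; proceeding", fold)
        model = build_model(config, montage, n_domains=len({w.subject_id for w in train_w}))
        model.fit(train_std, verbose=False)
        pred = model.predict(test_std)
        cm = ConfusionMatrix.from_labels([w.label for w in test_std], pred["labels"])
        fold_matrices.append(cm)
        fold_metrics.append(compute_metrics(cm))
        if verbose:
            print(f"fold {fold} ({sorted(test_subjects)}): acc={fold_metrics[-1]['accuracy']:.3f}")
    pooled = fold_matrices[0]
    for cm in fold_matrices[1:]:
        pooled = pooled + cm
    return CVReport(fold_metrics, fold_matrices, pooled)


def domain_probe_accuracy(
    features: np.ndarray,
    subject_ids: np.ndarray,
    seed: int = 0,
    test_fraction: float = 0.3,
) -> dict:
    """Accuracy of a freshly trained linear probe predicting the subject.

    Measures how much subject identity is still linearly decodable from
    frozen features: near ``1 / n_subjects`` (chance) means the
    representation is subject-invariant.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split
    from sklearn.preprocessing import StandardScaler

    subjects = sorted(set(np.asarray(subject_ids).tolist()))
    labels = np.array([subjects.index(s) for s in subject_ids])
    X_tr, X_te, y_tr, y_te = train_test_split(
        features, labels, test_size=test_fraction, random_state=seed, stratify=labels
    )
    scaler = StandardScaler().fit(X_tr)
    clf = LogisticRegression(max_iter=500, random_state=seed)
    clf.fit(scaler.transform(X_tr), y_tr)
    acc = float(clf.score(scaler.transform(X_te), y_te))
    return {"accuracy": acc, "chance": 1.0 / len(subjects), "n_domains": len(subjects)}
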