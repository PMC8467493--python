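"""Multi-class Matthews correlation coefficient, accuracies, and the
stratified cross-validation harness.

The multi-class MCC is the covariance form (the R_K statistic): with X the
N x K one-hot matrix of predictions and Y of actual classes,

    MCC = cov(X, Y) / sqrt(cov(X, X) * cov(Y, Y)),
    cov(A, B) = sum_{n,k} (A_nk - mean_k(A)) (B_nk - mean_k(B)).

It ranges over [-1, 1]: 1 is perfect prediction, 0 random, -1 complete
opposition (binary case). A zero variance term (all cells one class,
predicted as such) is defined as MCC = 0, mirroring the binary convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold

from cellrules.datamodel import LabeledDataset
from cellrules.smote import smote_balance


@dataclass
class EvalRecord:
    """One evaluation: MCC, overall accuracy, per-class accuracy (recall)."""

    mcc: float
    overall_accuracy: float
    per_class_accuracy: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def labels_to_indicator(labels, classes=None) -> np.ndarray:
    """One-hot N x K indicator matrix over a fixed class ordering."""
    labels = np.asarray(labels).astype(str)
    if classes is None:
        classes = sorted(set(labels))
    pos = {c: j for j, c in enumerate(classes)}
    out = np.zeros((len(labels), len(classes)))
    for i, l in enumerate(labels):
        out[i, pos[l]] = 1.0
    return out


def _check_indicator(M: np.ndarray, name: str) -> None:
    if M.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional")
    if not np.allclose(M.sum(axis=1), 1.0):
        raise ValueError(f"every row of {name} must sum to exactly 1")


def multiclass_mcc(X: np.ndarray, Y: np.ndarray) -> float:
    """Covariance-form MCC of predicted (X) vs actual (Y) indicator matrices."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("shape mismatch between predicted and actual matrices")
    _check_indicator(X, "X")
    _check_indicator(Y, "Y")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    cov_xy = float((Xc * Yc).sum())
    cov_xx = float((Xc * Xc).sum())
    cov_yy = float((Yc * Yc).sum())
    if cov_xx == 0.0 or cov_yy == 0.0:
        return 0.0
    return cov_xy / np.sqrt(cov_xx * cov_yy)


def mcc_from_labels(y_true, y_pred) -> float:
    """Multi-class MCC from label vectors (shared class ordering)."""
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    classes = sorted(set(y_true) | set(y_pred))
    if len(classes) < 2:
        return 0.0
    return multiclass_mcc(
        labels_to_indicator(y_pred, classes), labels_to_indicator(y_true, classes)
    )


def accuracies(y_true, y_pred) -> EvalRecord:
    """Overall accuracy, per-class accuracy (within-class recall), and MCC."""
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch")
    correct = y_true == y_pred
    per_class = {}
    for c in sorted(set(y_true)):
        m = y_true == c
        per_class[c] = float(correct[m].mean())
    return EvalRecord(
        mcc=mcc_from_labels(y_true, y_pred),
        overall_accuracy=float(correct.mean()),
        per_class_accuracy=per_class,
    )


def cross_validate(ds: LabeledDataset, genes, classifier_spec, folds: int = 10,
                   smote_policy: str = "within", smote_k: int = 5,
                   seed: int = 0) -> EvalRecord:
    """Stratified k-fold cross-validation restricted to a gene subset.

    Parameters
    ----------
    classifier_spec
        A ``ClassifierSpec`` (see the ifs module) or any callable
        ``seed -> estimator`` returning an object with fit/predict.
    smote_policy
        ``"within"`` (default, leakage-safe): each training fold is
        SMOTE-balanced before fitting, held-out cells stay untouched.
        ``"before"``: the whole dataset is balanced once before splitting
        (the study-faithful but leakage-prone variant).
        ``"none"``: no balancing.

    Held-out predictions are pooled over all folds into a single EvalRecord.
    """
    from cellrules.ifs import make_classifier  # local import avoids a cycle

    if smote_policy not in ("within", "before", "none"):
        raise ValueError(f"unknown smote_policy: {smote_policy!r}")
    work = ds.subset_genes(list(genes))
    if smote_policy == "before":
        work = smote_balance(work, k=smote_k, seed=seed).dataset

    y = work.labels.astype(str)
    X = work.matrix
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_true_all, y_pred_all = [], []
    rng = np.random.default_rng(seed)
    for train_idx, test_idx in skf.split(X, y):
        fold_seed = int(rng.integers(2**31 - 1))
        if smote_policy == "within":
            tr = smote_balance(work.subset_cells(train_idx), k=smote_k,
                               seed=fold_seed).dataset
            X_tr, y_tr = tr.matrix, tr.labels.astype(str)
        else:
            X_tr, y_tr = X[train_idx], y[train_idx]
        if callable(classifier_spec):
            clf = classifier_spec(fold_seed)
        else:
            clf = make_classifier(classifier_spec, seed=fold_seed)
        clf.fit(X_tr, y_tr)
        y_pred_all.append(clf.predict(X[test_idx]).astype(str))
        y_true_all.append(y[test_idx])

    return accuracies(np.concatenate(y_true_all), np.concatenate(y_pred_all))
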