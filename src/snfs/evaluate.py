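"""Hold-out evaluation: stratified splitting, RBF-SVM tuning, test metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from ._util import derive_seed
from .dataset import ExpressionDataset

__all__ = [
    "SplitSpec",
    "EvaluationReport",
    "stratified_holdout_split",
    "tune_rbf_svm",
    "evaluate_classifier",
]


@dataclass
class SplitSpec:
    """How to split a single matrix into train and test partitions."""

    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0
    positive_label: str | None = None

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class EvaluationReport:
    """Test-set classification metrics plus the matching training-set values."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int
    n_features: int
    positive_label: str
    params: dict
    train_accuracy: float
    train_auc: float
    metadata: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "FS": self.metadata.get("FS", ""),
            "CD": self.metadata.get("CD", ""),
            "CN": self.metadata.get("CN", ""),
            "Acc": round(self.accuracy, 4),
            "Sens": round(self.sensitivity, 4),
            "Spe": round(self.specificity, 4),
            "AUC": round(self.auc, 4),
            "FN": self.n_features,
        }


def stratified_holdout_split(data: ExpressionDataset,
                             spec: SplitSpec) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Single per-class proportional split, reproducible from the seed."""
    spec.validate()
    idx = np.arange(data.n_samples)
    stratify = data.labels if spec.stratified else None
    tr, te = train_test_split(idx, train_size=spec.train_fraction,
                              stratify=stratify, random_state=spec.seed)
    parts = []
    for sel in (np.sort(tr), np.sort(te)):
        part = ExpressionDataset(data.values[:, sel], data.gene_ids.copy(),
                                 data.sample_ids[sel], data.labels[sel])
        if part.classes.size != data.classes.size:
            raise ValueError("a class is empty in one partition; adjust train_fraction")
        parts.append(part)
    return parts[0], parts[1]


def _default_grids(n_features: int) -> tuple[np.ndarray, np.ndarray]:
    """Cost 2^-2..2^8; gamma feature-scaled, 2^j / p for j in -6..6.

    Centring gamma on 1/p (the libsvm default scale for unit-variance
    features) keeps the grid informative from tens to tens of thousands of
    genes, where a fixed absolute grid collapses the kernel to the identity.
    """
    cost = 2.0 ** np.arange(-2, 9)
    gamma = 2.0 ** np.arange(-6, 7) / n_features
    return cost, gamma


def tune_rbf_svm(train: ExpressionDataset, feature_subset=None, cost_grid=None,
                 gamma_grid=None, n_folds: int = 10, seed: int = 0) -> dict:
    """Grid-search (cost, gamma) of an RBF SVM by stratified k-fold CV.

    Returns the pair with the highest mean CV accuracy; ties go to the
    smallest cost, then the smallest gamma.  Kernels are evaluated from a
    single precomputed squared-distance matrix, so the full grid costs one
    distance computation plus cheap exponentiations.
    """
    sub = train if feature_subset is None else train.subset(feature_subset)
    X = np.ascontiguousarray(sub.X)
    y = sub.labels
    _, counts = np.unique(y, return_counts=True)
    if counts.size != 2:
        raise ValueError("two-class labels required")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot form {n_folds} folds"
        )
    if cost_grid is None or gamma_grid is None:
        dc, dg = _default_grids(X.shape[1])
        cost_grid = dc if cost_grid is None else np.asarray(cost_grid, dtype=float)
        gamma_grid = dg if gamma_grid is None else np.asarray(gamma_grid, dtype=float)
    sq = (X**2).sum(axis=1)
    D = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=derive_seed(seed, "cv"))
    folds = list(skf.split(X, y))
    acc = np.zeros((len(gamma_grid), len(cost_grid)))
    for gi, gamma in enumerate(gamma_grid):
        K = np.exp(-gamma * D)
        for tr, te in folds:
            K_tr = K[np.ix_(tr, tr)]
            K_te = K[np.ix_(te, tr)]
            for ci, cost in enumerate(cost_grid):
                clf = SVC(C=cost, kernel="precomputed")
                clf.fit(K_tr, y[tr])
                acc[gi, ci] += float(np.mean(clf.predict(K_te) == y[te]))
    acc /= len(folds)
    best = acc.max()
    winners = np.argwhere(acc >= best - 1e-12)
    order = sorted(
        (float(cost_grid[ci]), float(gamma_grid[gi])) for gi, ci in winners
    )
    cost, gamma = order[0]
    return {"cost": cost, "gamma": gamma, "cv_accuracy": float(best)}


def _confusion_metrics(y_true, y_pred, scores, positive):
    pos = y_true == positive
    pred_pos = y_pred == positive
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    accuracy = (tp + tn) / y_true.size
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    auc = float(roc_auc_score(pos, scores))
    return accuracy, sensitivity, specificity, auc, tp, fp, tn, fn


def evaluate_classifier(train: ExpressionDataset, test: ExpressionDataset,
                        feature_subset, params: dict,
                        positive_label: str | None = None,
                        metadata: dict | None = None) -> EvaluationReport:
    """Fit an RBF SVM on the selected genes and score the held-out test set.

    AUC comes from the continuous decision values (ties contribute half per
    positive-negative pair); sensitivity/specificity use the declared
    positive label, defaulting to the minority training class (ties broken
    toward the lexicographically last label).
    """
    feature_subset = np.asarray(feature_subset, dtype=str)
    if feature_subset.size == 0:
        raise ValueError("feature subset is empty")
    tr = train.subset(feature_subset)
    te = test.subset(feature_subset)
    classes, counts = np.unique(tr.labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("two-class labels required")
    if positive_label is None:
        minority = counts.min()
        positive_label = str(sorted(classes[counts == minority])[-1])
    clf = SVC(C=params["cost"], gamma=params["gamma"], kernel="rbf")
    clf.fit(tr.X, tr.labels)

    def _scores(X):
        s = clf.decision_function(X)
        return s if str(clf.classes_[1]) == positive_label else -s

    acc, sens, spec, auc, tp, fp, tn, fn = _confusion_metrics(
        te.labels, clf.predict(te.X), _scores(te.X), positive_label
    )
    tr_acc, _, _, tr_auc, *_ = _confusion_metrics(
        tr.labels, clf.predict(tr.X), _scores(tr.X), positive_label
    )
    return EvaluationReport(
        accuracy=acc, sensitivity=sens, specificity=spec, auc=auc,
        tp=tp, fp=fp, tn=tn, fn=fn, n_features=int(feature_subset.size),
        positive_label=positive_label, params=dict(params),
        train_accuracy=tr_acc, train_auc=tr_auc, metadata=metadata or {},
    )
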