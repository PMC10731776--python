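"""Pair classification: features, gradient-boosted trees, CV, ranking.

Each candidate (microbe, disease) pair is represented by the concatenation
of the two node embeddings. Known associations are the positives; an equal
number of never-observed cells is drawn uniformly as negatives (the ratio
is configurable). A gradient-boosted-tree classifier with library-default
parameters scores pairs under stratified tenfold cross-validation, and six
metrics are reported per fold and on average: AUROC, AUPR, F1, precision,
recall, accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .containers import AssociationMatrix

__all__ = [
    "PairDataset",
    "EvalReport",
    "AssociationClassifier",
    "build_pairs",
    "compute_metrics",
    "crossval",
    "rank_candidates",
]

METRIC_NAMES = ("auroc", "aupr", "f1", "precision", "recall", "accuracy")


@dataclass
class PairDataset:
    features: np.ndarray
    labels: np.ndarray
    pair_ids: list[tuple[str, str]]
    fold_assignment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pair_ids) != len(self.labels) or len(self.labels) != len(self.features):
            raise ValueError("features, labels and pair_ids disagree in length")
        if len(set(self.pair_ids)) != len(self.pair_ids):
            raise ValueError("duplicated (microbe, disease) pair")


@dataclass
class EvalReport:
    per_fold: list[dict[str, float]]
    threshold: float
    mean: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.mean = {
            k: float(np.mean([f[k] for f in self.per_fold])) for k in METRIC_NAMES
        }

    def to_json(self, path=None) -> str:
        payload = {
            "threshold": self.threshold,
            "per_fold": self.per_fold,
            "mean": self.mean,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


class AssociationClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted-tree pair classifier (XGBoost with library-default
    parameters, per the reference protocol). Thin sklearn wrapper so it
    composes with model selection."""

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, X, y):
        self.model_ = XGBClassifier(random_state=self.random_state, n_jobs=1)
        self.model_.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def decision_scores(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.decision_scores(X) >= 0.5).astype(int)


def build_pairs(A: AssociationMatrix, Zm: np.ndarray, Zd: np.ndarray,
                negative_ratio: float = 1.0, seed: int = 0) -> PairDataset:
    """All positive cells plus uniformly sampled negatives from the zero
    cells (without replacement), count = round(ratio * positives);
    deterministic given the seed."""
    Zm = np.asarray(Zm, dtype=float)
    Zd = np.asarray(Zd, dtype=float)
    if Zm.shape[0] != A.n_microbes or Zd.shape[0] != A.n_diseases:
        raise ValueError("embeddings must cover every microbe and disease")
    pos = np.argwhere(A.values == 1)
    zero = np.argwhere(A.values == 0)
    n_neg = int(round(negative_ratio * len(pos)))
    if n_neg > len(zero):
        raise ValueError(
            f"negative_ratio {negative_ratio} requires {n_neg} negatives but "
            f"only {len(zero)} zero cells exist"
        )
    rng = np.random.default_rng(seed)
    neg = zero[rng.choice(len(zero), size=n_neg, replace=False)] if n_neg else \
        np.empty((0, 2), dtype=int)
    cells = np.vstack([pos, neg])
    labels = np.concatenate([np.ones(len(pos), dtype=int),
                             np.zeros(len(neg), dtype=int)])
    feats = np.hstack([Zm[cells[:, 0]], Zd[cells[:, 1]]])
    ids = [(A.row_labels[i], A.col_labels[j]) for i, j in cells]
    return PairDataset(feats, labels, ids)


def compute_metrics(y_true, scores, threshold: float = 0.5) -> dict[str, float]:
    """The six evaluation metrics from scores in [0, 1]; the thresholded
    four use the given decision threshold."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= threshold).astype(int)
    return {
        "auroc": float(roc_auc_score(y_true, scores)),
        "aupr": float(average_precision_score(y_true, scores)),
        "f1": float(f1_score(y_true, pred, zero_division=0)),
        "precision": float(precision_score(y_true, pred, zero_division=0)),
        "recall": float(recall_score(y_true, pred, zero_division=0)),
        "accuracy": float(accuracy_score(y_true, pred)),
    }


def crossval(ds: PairDataset, folds: int = 10, threshold: float = 0.5,
             seed: int = 0) -> EvalReport:
    """Stratified k-fold CV of the gradient-boosted pair classifier."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_assignment = np.full(len(ds.labels), -1, dtype=int)
    per_fold = []
    for k, (tr, te) in enumerate(skf.split(ds.features, ds.labels)):
        fold_assignment[te] = k
        if len(np.unique(ds.labels[te])) < 2:
            raise ValueError(f"fold {k} contains a single class")
        clf = AssociationClassifier(random_state=seed).fit(
            ds.features[tr], ds.labels[tr]
        )
        scores = clf.decision_scores(ds.features[te])
        per_fold.append(compute_metrics(ds.labels[te], scores, threshold))
    ds.fold_assignment = fold_assignment
    return EvalReport(per_fold, threshold)


def rank_candidates(A: AssociationMatrix, Zm: np.ndarray, Zd: np.ndarray,
                    model: AssociationClassifier, disease_id: str,
                    top_k: int = 20) -> list[tuple[str, float]]:
    """Score every microbe not yet associated with the disease and return
    the top_k by predicted association probability (ties by label)."""
    j = A.col_labels.index(disease_id)
    candidates = [i for i in range(A.n_microbes) if A.values[i, j] == 0]
    if not candidates or top_k <= 0:
        return []
    feats = np.hstack([
        np.asarray(Zm)[candidates],
        np.tile(np.asarray(Zd)[j], (len(candidates), 1)),
    ])
    scores = model.decision_scores(feats)
    order = sorted(
        range(len(candidates)),
        key=lambda idx: (-scores[idx], A.row_labels[candidates[idx]]),
    )
    return [(A.row_labels[candidates[idx]], float(scores[idx]))
            for idx in order[:top_k]]
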