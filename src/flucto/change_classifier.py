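"""Random-forest classification of the degree of UPDRS-III change.

An ensemble of T = 100 Gini decision trees is bagged on the incremental
feature vectors: each tree trains on a random two-thirds draw (with
replacement) of the pairs, and sqrt(N) feature candidates per split.  The
out-of-bag (OOB) samples of each tree provide an internal generalisation
estimate; ``oob_error_curve`` traces it as the ensemble grows, mirroring
the usual RF diagnostic.

Prediction is by majority vote over the trees; vote ties break toward the
higher severity degree (the clinically conservative choice).  Grouped
importances average the per-feature impurity-decrease importances within
each of the five incremental-feature blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .incremental_features import BLOCK_NAMES, block_slices

__all__ = [
    "ClassifierConfig",
    "ChangeModel",
    "train_change_classifier",
    "predict_change",
    "predict_change_batch",
    "oob_error_curve",
    "grouped_feature_importance",
]

SEVERITY_CLASSES = (0, 1, 2, 3)


@dataclass(frozen=True)
class ClassifierConfig:
    """Random-forest settings: T trees, 2/3 bagging, sqrt(N) features/split."""

    n_trees: int = 100
    bag_fraction: float = 2.0 / 3.0
    max_features: str = "sqrt"
    class_weight: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag_fraction must be in (0, 1]")


@dataclass
class ChangeModel:
    """Trained ensemble plus the metadata needed downstream.

    k is the fixed cluster count the training vectors were built with; it
    fixes the feature-block boundaries used by the grouped importances.
    """

    forest: RandomForestClassifier
    config: ClassifierConfig
    k: Optional[int] = None
    n_features: int = 0

    @property
    def classes_(self) -> np.ndarray:
        return self.forest.classes_


def train_change_classifier(
    X, y, cfg: ClassifierConfig = ClassifierConfig(), k: Optional[int] = None
) -> ChangeModel:
    """Fit the bagged ensemble; deterministic for a given seed.

    Requires at least two classes and finite features; per-tree bags are
    retained by the forest for OOB computation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, d) with matching y")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains NaN or infinite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        criterion="gini",
        max_features=cfg.max_features,
        bootstrap=True,
        max_samples=cfg.bag_fraction,
        class_weight=cfg.class_weight,
        random_state=cfg.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return ChangeModel(forest=forest, config=cfg, k=k, n_features=X.shape[1])


def _majority_label(votes: np.ndarray, classes: np.ndarray) -> int:
    """Label with the most votes; ties break toward the higher severity."""
    best = votes.max()
    return int(max(c for c, v in zip(classes, votes) if v == best))


def _tree_predictions(model: ChangeModel, X: np.ndarray) -> np.ndarray:
    """(n_trees, n_samples) matrix of per-tree predicted labels."""
    return np.stack([est.predict(X) for est in model.forest.estimators_]).astype(int)


def predict_change(model: ChangeModel, f) -> tuple[int, np.ndarray]:
    """Majority-vote prediction for one vector.

    Returns (label, vote fractions over severities 0–3).  Fractions of
    classes absent from training are 0; ties break toward the higher label.
    """
    f = np.asarray(f, dtype=float)
    if f.ndim != 1 or len(f) != model.n_features:
        raise ValueError(
            f"feature vector length {len(f)} does not match training ({model.n_features})"
        )
    preds = _tree_predictions(model, f[None, :])[:, 0]
    classes = model.classes_
    votes = np.array([np.count_nonzero(preds == c) for c in classes])
    label = _majority_label(votes, classes)
    fractions = np.zeros(len(SEVERITY_CLASSES))
    for c, v in zip(classes, votes):
        fractions[int(c)] = v / len(preds)
    return label, fractions


def predict_change_batch(model: ChangeModel, X) -> np.ndarray:
    """Majority-vote predictions for many vectors (tie → higher label)."""
    X = np.asarray(X, dtype=float)
    preds = _tree_predictions(model, X)
    classes = model.classes_
    out = np.empty(X.shape[0], dtype=int)
    for i in range(X.shape[0]):
        votes = np.array([np.count_nonzero(preds[:, i] == c) for c in classes])
        out[i] = _majority_label(votes, classes)
    return out


def oob_error_curve(model: ChangeModel, X, y) -> np.ndarray:
    """OOB misclassification rate using the first t trees, t = 1..T.

    For each sample, only trees whose bag excluded it vote; samples with no
    OOB tree at ensemble size t are left out of that error estimate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    forest = model.forest
    classes = model.classes_
    n_classes = len(classes)
    class_index = {int(c): i for i, c in enumerate(classes)}
    preds = _tree_predictions(model, X)

    in_bag = np.zeros((forest.n_estimators, n), dtype=bool)
    for t, sample_idx in enumerate(forest.estimators_samples_):
        in_bag[t, np.asarray(sample_idx)] = True

    votes = np.zeros((n, n_classes), dtype=int)
    errors = np.empty(forest.n_estimators)
    for t in range(forest.n_estimators):
        oob = ~in_bag[t]
        for i in np.flatnonzero(oob):
            votes[i, class_index[int(preds[t, i])]] += 1
        has_vote = votes.sum(axis=1) > 0
        if not has_vote.any():
            errors[t] = np.nan
            continue
        # argmax with ties toward the higher class
        pred = classes[
            n_classes - 1 - np.argmax(votes[has_vote][:, ::-1], axis=1)
        ]
        errors[t] = float(np.mean(pred != y[has_vote]))
    return errors


def grouped_feature_importance(model: ChangeModel) -> dict[str, float]:
    """Impurity-decrease importance averaged within each incremental block.

    Requires the model to have been trained with a known K; empty blocks
    (K = 1 has no centroid-distance pairs) report 0.
    """
    if model.k is None:
        raise ValueError("model was trained without block boundaries (k unknown)")
    imp = model.forest.feature_importances_
    out = {}
    for name, sl in block_slices(model.k).items():
        vals = imp[sl]
        out[name] = float(vals.mean()) if len(vals) else 0.0
    return out
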