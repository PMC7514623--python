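"""Leave-one-subject-out evaluation of the full severity pipeline.

For every fold one subject is held out entirely: the cluster count K is the
median of free SOTM fits over the *training* rounds only, the random forest
is trained on the training subjects' incremental vectors, and the held-out
subject's round pairs are then predicted — so no held-out information can
leak into model selection or training.  The harness reports a pairwise
confusion matrix (degrees of UPDRS-III change) and per-subject severity
decisions, together with the per-fold K values and which rounds each fold
trained on.

Round-level quantities (symptom feature matrices, free-fit cluster counts,
fixed-K models, pair vectors) depend only on the round itself, so they are
cached across folds; fold structure is unaffected.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .change_classifier import (
    ChangeModel,
    ClassifierConfig,
    predict_change_batch,
    train_change_classifier,
)
from .incremental_features import IncrementalFeatureVector, build_incremental_vector
from .io_preproc import (
    INC,
    Inconclusive,
    PreprocConfig,
    Round,
    RoundPair,
    Site,
    bandpass_filter,
    pair_rounds,
    segment_windows,
)
from .severity_decision import (
    ChangeDistribution,
    DecisionConfig,
    SeverityDecision,
    decide_severity,
)
from .sotm import ClusterModel, SotmParams, fit_sotm, fit_sotm_fixed_k
from .symptom_features import extract_feature_matrix
from .synthetic_data import Cohort, SyntheticSubject

log = logging.getLogger(__name__)

__all__ = [
    "EvalConfig",
    "ConfusionMatrix",
    "LosoPairwiseResult",
    "LosoSeverityResult",
    "LosoResult",
    "round_feature_matrix",
    "pair_vector",
    "loso_evaluation",
    "loso_pairwise_evaluation",
    "loso_severity_evaluation",
    "majority_class_baseline",
]


@dataclass(frozen=True)
class EvalConfig:
    """End-to-end pipeline configuration for the LOSO harness.

    fusion selects the symptom-feature layout: "fused" concatenates both
    sites (132-dim vectors), "wrist"/"ankle" use a single site (66-dim).
    """

    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    sotm: SotmParams = field(default_factory=SotmParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    decision: DecisionConfig = field(default_factory=DecisionConfig)
    fusion: str = "fused"

    def __post_init__(self) -> None:
        if self.fusion not in ("fused", "wrist", "ankle"):
            raise ValueError("fusion must be 'fused', 'wrist' or 'ankle'")


@dataclass
class ConfusionMatrix:
    """Integer count matrix; rows are true degrees, columns predicted."""

    counts: np.ndarray
    labels: tuple[int, ...] = (0, 1, 2, 3)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError("counts shape must match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_pairs(
        cls, truths: Sequence[int], preds: Sequence[int], labels=(0, 1, 2, 3)
    ) -> "ConfusionMatrix":
        n = len(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((n, n), dtype=int)
        for t, p in zip(truths, preds, strict=True):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, labels=tuple(labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)


@dataclass
class LosoPairwiseResult:
    confusion: ConfusionMatrix
    fold_k: dict[str, int]
    fold_training_rounds: dict[str, list[str]]
    predictions: list[tuple[str, int, int]]  # (pair id, truth, prediction)

    @property
    def accuracy(self) -> float:
        return self.confusion.accuracy


@dataclass
class LosoSeverityResult:
    decisions: dict[str, SeverityDecision]
    truths: dict[str, Union[int, Inconclusive]]

    @property
    def accuracy(self) -> float:
        correct = sum(
            1
            for sid, dec in self.decisions.items()
            if dec.s is self.truths[sid] or dec.s == self.truths[sid]
        )
        return correct / len(self.decisions)


@dataclass
class LosoResult:
    pairwise: LosoPairwiseResult
    severity: LosoSeverityResult
    #: model and training set of the first fold, kept for diagnostics
    #: (OOB curve, grouped importances)
    example_model: ChangeModel
    example_training: tuple[np.ndarray, np.ndarray]


def round_feature_matrix(
    rnd: Round,
    preproc: PreprocConfig = PreprocConfig(),
    fusion: str = "fused",
    prefiltered: bool = False,
) -> np.ndarray:
    """Symptom-feature matrix of one round: (n_windows, 66 or 132).

    Each site's recording is band-pass filtered and windowed; in fused mode
    the two sites' synchronous windows are concatenated feature-wise.
    """
    sites = (
        [Site.WRIST, Site.ANKLE] if fusion == "fused" else [Site(fusion)]
    )
    blocks = []
    for site in sites:
        if site not in rnd.recordings:
            raise ValueError(f"round {rnd.round_id} has no {site.value} recording")
        rec = rnd.recordings[site]
        if not prefiltered:
            rec = bandpass_filter(rec, preproc)
        windows = segment_windows(rec, preproc)
        if len(windows) == 0:
            raise ValueError(
                f"round {rnd.round_id} is shorter than one window "
                f"({rec.duration_s:.2f} s < {preproc.window_s} s)"
            )
        blocks.append(extract_feature_matrix(windows, rec.fs))
    if len({len(b) for b in blocks}) != 1:
        raise ValueError("sites yielded differing window counts")
    return np.hstack(blocks)


def pair_vector(
    model_i: ClusterModel, model_j: ClusterModel
) -> IncrementalFeatureVector:
    """Incremental feature vector of a round pair from its two models."""
    return build_incremental_vector(model_i, model_j)


def _round_seed(round_id: str, base_seed: int) -> int:
    return (zlib.crc32(round_id.encode()) ^ base_seed) % (2**31)


class _PipelineCache:
    """Per-round/per-pair computations shared across folds (no fold state)."""

    def __init__(self, cfg: EvalConfig) -> None:
        self.cfg = cfg
        self.features: dict[str, np.ndarray] = {}
        self.free_k: dict[str, int] = {}
        self.fixed_models: dict[tuple[str, int], ClusterModel] = {}
        self.vectors: dict[tuple[str, int], np.ndarray] = {}

    def feature_matrix(self, rnd: Round) -> np.ndarray:
        if rnd.round_id not in self.features:
            self.features[rnd.round_id] = round_feature_matrix(
                rnd, self.cfg.preproc, self.cfg.fusion
            )
        return self.features[rnd.round_id]

    def free_cluster_count(self, rnd: Round) -> int:
        if rnd.round_id not in self.free_k:
            params = replace(
                self.cfg.sotm, seed=_round_seed(rnd.round_id, self.cfg.sotm.seed)
            )
            self.free_k[rnd.round_id] = fit_sotm(self.feature_matrix(rnd), params).k
        return self.free_k[rnd.round_id]

    def fixed_model(self, rnd: Round, k: int) -> ClusterModel:
        key = (rnd.round_id, k)
        if key not in self.fixed_models:
            params = replace(
                self.cfg.sotm, seed=_round_seed(rnd.round_id, self.cfg.sotm.seed)
            )
            self.fixed_models[key] = fit_sotm_fixed_k(
                self.feature_matrix(rnd), k, params
            )
        return self.fixed_models[key]

    def pair_vector(self, pair: RoundPair, k: int) -> np.ndarray:
        key = (pair.pair_id, k)
        if key not in self.vectors:
            vec = build_incremental_vector(
                self.fixed_model(pair.round_i, k), self.fixed_model(pair.round_j, k)
            )
            self.vectors[key] = vec.values
        return self.vectors[key]


def _select_k_for_fold(
    training_subjects: Sequence[SyntheticSubject], cache: _PipelineCache
) -> int:
    import math

    counts = [
        cache.free_cluster_count(rnd)
        for sub in training_subjects
        for rnd in sub.rounds
    ]
    med = float(np.median(counts))
    return max(1, math.ceil(med - 0.5))


def majority_class_baseline(labels: Sequence[int]) -> float:
    """Accuracy of always predicting the most frequent pair label."""
    labels = list(labels)
    return max(labels.count(c) for c in set(labels)) / len(labels)


def loso_evaluation(dataset: Cohort, cfg: EvalConfig = EvalConfig()) -> LosoResult:
    """Run the full leave-one-subject-out evaluation once.

    Returns pairwise and subject-level results plus the first fold's model
    and training set for ensemble diagnostics.
    """
    subjects = dataset.subjects
    if len(subjects) < 2:
        raise ValueError("need at least two subjects for LOSO evaluation")
    cache = _PipelineCache(cfg)

    subject_pairs: dict[str, list[RoundPair]] = {}
    for sub in subjects:
        pairs = [p for p in pair_rounds(sub.rounds) if p.severity_label is not None]
        if len(sub.rounds) >= 2 and not pairs:
            log.warning("subject %s has rounds but no labeled pairs", sub.subject_id)
        subject_pairs[sub.subject_id] = pairs

    fold_k: dict[str, int] = {}
    fold_rounds: dict[str, list[str]] = {}
    predictions: list[tuple[str, int, int]] = []
    truths_all: list[int] = []
    preds_all: list[int] = []
    decisions: dict[str, SeverityDecision] = {}
    truths: dict[str, Union[int, Inconclusive]] = {}
    example_model: Optional[ChangeModel] = None
    example_training: Optional[tuple[np.ndarray, np.ndarray]] = None

    for held_out in subjects:
        training = [s for s in subjects if s.subject_id != held_out.subject_id]
        train_pairs = [p for s in training for p in subject_pairs[s.subject_id]]
        y_train = np.array([p.severity_label for p in train_pairs])
        if len(np.unique(y_train)) < 2:
            raise ValueError(
                f"training fold for held-out subject {held_out.subject_id} "
                "contains a single change class"
            )
        k = _select_k_for_fold(training, cache)
        fold_k[held_out.subject_id] = k
        fold_rounds[held_out.subject_id] = [
            rnd.round_id for s in training for rnd in s.rounds
        ]
        x_train = np.stack([cache.pair_vector(p, k) for p in train_pairs])
        model = train_change_classifier(x_train, y_train, cfg.classifier, k=k)
        if example_model is None:
            example_model = model
            example_training = (x_train, y_train)

        held_pairs = subject_pairs[held_out.subject_id]
        if held_pairs:
            x_test = np.stack([cache.pair_vector(p, k) for p in held_pairs])
            preds = predict_change_batch(model, x_test)
            for pair, pred in zip(held_pairs, preds):
                predictions.append((pair.pair_id, pair.severity_label, int(pred)))
                truths_all.append(pair.severity_label)
                preds_all.append(int(pred))

        # subject-level decision: all pairs of the held-out subject's full
        # day timeline (scored and unscored rounds alike)
        timeline_pairs = pair_rounds(held_out.timeline_rounds)
        if timeline_pairs:
            x_day = np.stack([cache.pair_vector(p, k) for p in timeline_pairs])
            day_preds = predict_change_batch(model, x_day)
            dist = ChangeDistribution.from_predictions(day_preds)
            decisions[held_out.subject_id] = decide_severity(dist, cfg.decision)
        else:
            # single round: no pairs, no decision possible
            decisions[held_out.subject_id] = SeverityDecision(
                s=INC, p=(None, None, None, None), distribution=None
            )
        truths[held_out.subject_id] = held_out.true_severity

    confusion = ConfusionMatrix.from_pairs(truths_all, preds_all)
    assert confusion.total == len(predictions)
    pairwise = LosoPairwiseResult(
        confusion=confusion,
        fold_k=fold_k,
        fold_training_rounds=fold_rounds,
        predictions=predictions,
    )
    severity = LosoSeverityResult(decisions=decisions, truths=truths)
    assert example_model is not None and example_training is not None
    return LosoResult(
        pairwise=pairwise,
        severity=severity,
        example_model=example_model,
        example_training=example_training,
    )


def loso_pairwise_evaluation(
    dataset: Cohort, cfg: EvalConfig = EvalConfig()
) -> LosoPairwiseResult:
    """Confusion matrix and accuracy over all held-out round pairs."""
    return loso_evaluation(dataset, cfg).pairwise


def loso_severity_evaluation(
    dataset: Cohort, cfg: EvalConfig = EvalConfig()
) -> LosoSeverityResult:
    """Per-subject severity decisions; INC predicted for INC truth counts
    as correct."""
    return loso_evaluation(dataset, cfg).severity
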