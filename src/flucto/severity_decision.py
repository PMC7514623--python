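"""Histogram-based subject-level severity decision.

The trained change classifier labels every pair of a subject's 3-min rounds
with a degree of UPDRS-III change (0–3); the counts (d0, d1, d2, d3) of
those labels form the subject's change distribution.  The decision rule is
driven by the ratio (d1 + d2 + d3) / d0:

* ratio > 0.3 — the subject fluctuates: d0 (time spent fully ON or fully
  OFF) is excluded, the remaining counts are normalised into percentages
  p1..p3 and the severity S is the arg-max degree (ties toward the higher,
  clinically conservative degree);
* ratio ≤ 0.2 — degree-0 pairs dominate: S = 0 with p0 = 100%;
* otherwise — inconclusive (INC): the data support neither conclusion.

d0 = 0 counts as an infinite ratio (first branch).  Percentages are
reported rounded to the nearest integer.  The percentage denominator in the
first branch is d1 + d2 + d3, which reproduces the published per-subject
percentages; the variant that keeps d0 in the denominator is available via
``DecisionConfig.pseudocode_denominator``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .io_preproc import (
    INC,
    GyroRecording,
    Inconclusive,
    PreprocConfig,
    Site,
    bandpass_filter,
    merge_site_rounds,
    pair_rounds,
    segment_rounds,
)

__all__ = [
    "ChangeDistribution",
    "DecisionConfig",
    "SeverityDecision",
    "severity_ratio",
    "decide_severity",
    "decide_for_subject",
]


@dataclass(frozen=True)
class ChangeDistribution:
    """Counts of round pairs predicted as each degree of change."""

    d0: int
    d1: int
    d2: int
    d3: int

    def __post_init__(self) -> None:
        if min(self.d0, self.d1, self.d2, self.d3) < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, labels: Sequence[int]) -> "ChangeDistribution":
        counts = [0, 0, 0, 0]
        for lab in labels:
            counts[int(lab)] += 1
        return cls(*counts)

    @property
    def total(self) -> int:
        return self.d0 + self.d1 + self.d2 + self.d3

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.d0, self.d1, self.d2, self.d3)


@dataclass(frozen=True)
class DecisionConfig:
    """Decision-rule thresholds on the nonzero-to-zero count ratio."""

    hi_ratio: float = 0.3
    lo_ratio: float = 0.2
    pseudocode_denominator: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.lo_ratio < self.hi_ratio:
            raise ValueError("require 0 < lo_ratio < hi_ratio")


@dataclass
class SeverityDecision:
    """Decision output: severity S (0–3 or INC) and percentages p0..p3.

    Unavailable percentages are None (printed N/A); available ones are
    integers that sum to 100 up to rounding.
    """

    s: Union[int, Inconclusive]
    p: tuple[Optional[int], Optional[int], Optional[int], Optional[int]]
    distribution: Optional[ChangeDistribution] = None


def severity_ratio(d: ChangeDistribution) -> float:
    """(d1 + d2 + d3) / d0; +inf when d0 = 0.  All-zero counts are invalid."""
    if d.total == 0:
        raise ValueError("change distribution has no counts")
    nonzero = d.d1 + d.d2 + d.d3
    if d.d0 == 0:
        return math.inf
    return nonzero / d.d0


def _pct(x: float) -> int:
    return int(math.floor(x + 0.5))


def decide_severity(
    d: ChangeDistribution, cfg: DecisionConfig = DecisionConfig()
) -> SeverityDecision:
    """Apply the histogram decision rule to a change distribution."""
    ratio = severity_ratio(d)
    counts = d.as_tuple()
    if ratio > cfg.hi_ratio:
        denom = d.total if cfg.pseudocode_denominator else (d.d1 + d.d2 + d.d3)
        ps = [_pct(100.0 * counts[s] / denom) for s in (1, 2, 3)]
        best = max((p, s) for s, p in zip((1, 2, 3), ps))[1]
        return SeverityDecision(s=best, p=(None, ps[0], ps[1], ps[2]), distribution=d)
    if ratio <= cfg.lo_ratio:
        return SeverityDecision(s=0, p=(100, None, None, None), distribution=d)
    return SeverityDecision(s=INC, p=(None, None, None, None), distribution=d)


def decide_for_subject(
    recordings: dict[Site, GyroRecording],
    model,
    preproc: PreprocConfig = PreprocConfig(),
    sotm_params=None,
    cfg: DecisionConfig = DecisionConfig(),
    fusion: str = "fused",
) -> SeverityDecision:
    """Full subject pipeline: rounds → pairs → predicted changes → decision.

    The (multi-site) recording is band-pass filtered, segmented into 3-min
    rounds, all round pairs are mapped to incremental feature vectors with
    the model's fixed K, classified, and the resulting change distribution
    is fed to ``decide_severity``.
    """
    from .evaluation import pair_vector, round_feature_matrix  # cycle-free at runtime
    from .sotm import SotmParams, fit_sotm_fixed_k

    if sotm_params is None:
        sotm_params = SotmParams()
    per_site_rounds = []
    for site, rec in recordings.items():
        filtered = bandpass_filter(rec, preproc)
        per_site_rounds.append(segment_rounds(filtered, preproc))
    rounds = merge_site_rounds(per_site_rounds)
    if len(rounds) < 2:
        raise ValueError(
            f"need at least two rounds for a decision, got {len(rounds)}"
        )
    if model.k is None:
        raise ValueError("model carries no fixed cluster count K")
    features = {
        r.round_id: round_feature_matrix(r, preproc, fusion, prefiltered=True)
        for r in rounds
    }
    models = {
        rid: fit_sotm_fixed_k(mat, model.k, sotm_params)
        for rid, mat in features.items()
    }
    from .change_classifier import predict_change

    labels = []
    for pair in pair_rounds(rounds):
        vec = pair_vector(models[pair.round_i.round_id], models[pair.round_j.round_id])
        label, _ = predict_change(model, vec.values)
        labels.append(label)
    return decide_severity(ChangeDistribution.from_predictions(labels), cfg)
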