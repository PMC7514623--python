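"""Incremental features: how cluster topology changes between two rounds.

Given fixed-K cluster models of the symptom-feature vectors of rounds I and
J, the incremental feature vector concatenates five blocks (all Euclidean
distances, hence non-negative):

1. pairwise centroid distances within round I           — C(K,2) values
2. within-cluster spreads of round I                    — K values
3. pairwise centroid distances within round J           — C(K,2) values
4. within-cluster spreads of round J                    — K values
5. cross-round shifts between rank-matched centroids    — K values

for a total of N = 2·C(K,2) + 3K (35 when K = 5).  Before pairing, each
model's clusters are sorted by descending centroid norm (ties broken by
creation order), so block 5 matches clusters across rounds by sorted rank.
The within-cluster spread of cluster k is sum_n d(v_n, C_k) / (m_k − 1)
over its m_k members; a singleton cluster has spread 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .sotm import ClusterModel

__all__ = [
    "IncrementalFeatureVector",
    "vector_length",
    "block_slices",
    "block_names",
    "sort_clusters",
    "centroid_distances",
    "within_cluster_spread",
    "cross_round_shift",
    "build_incremental_vector",
]

#: Canonical block order.
BLOCK_NAMES = (
    "centroid_distances_i",
    "within_spread_i",
    "centroid_distances_j",
    "within_spread_j",
    "cross_round_shift",
)


def vector_length(k: int) -> int:
    """N = 2·C(K,2) + 3K."""
    return k * (k - 1) + 3 * k


def block_slices(k: int) -> dict[str, slice]:
    """Start/stop of each of the five blocks within the feature vector."""
    sizes = [k * (k - 1) // 2, k, k * (k - 1) // 2, k, k]
    slices = {}
    start = 0
    for name, size in zip(BLOCK_NAMES, sizes):
        slices[name] = slice(start, start + size)
        start += size
    return slices


def block_names() -> tuple[str, ...]:
    return BLOCK_NAMES


@dataclass
class IncrementalFeatureVector:
    """The concatenated incremental feature vector of one round pair."""

    values: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != vector_length(self.k):
            raise ValueError(
                f"expected {vector_length(self.k)} values for K={self.k}, "
                f"got {len(self.values)}"
            )

    def block(self, name: str) -> np.ndarray:
        return self.values[block_slices(self.k)[name]]


def sort_clusters(model: ClusterModel) -> ClusterModel:
    """Order clusters by descending centroid norm, ties by creation order."""
    norms = np.linalg.norm(model.centroids, axis=1)
    order = sorted(range(model.k), key=lambda i: (-norms[i], model.creation_order[i]))
    return replace(
        model,
        centroids=model.centroids[order],
        memberships=[model.memberships[i] for i in order],
        creation_order=[model.creation_order[i] for i in order],
    )


def centroid_distances(model: ClusterModel) -> np.ndarray:
    """Pairwise centroid distances d(C_a, C_b) for a < b, in index order."""
    c = model.centroids
    return np.array(
        [
            float(np.linalg.norm(c[a] - c[b]))
            for a, b in itertools.combinations(range(len(c)), 2)
        ]
    )


def within_cluster_spread(model: ClusterModel) -> np.ndarray:
    """Per-cluster spread: sum of member–centroid distances over (m_k − 1).

    Clusters with at most one member (including empty ones) have spread 0.
    """
    spreads = []
    for k in range(model.k):
        members = model.members(k)
        m = len(members)
        if m <= 1:
            spreads.append(0.0)
            continue
        d = np.linalg.norm(members - model.centroids[k], axis=1)
        spreads.append(float(d.sum() / (m - 1)))
    return np.array(spreads)


def cross_round_shift(model_i: ClusterModel, model_j: ClusterModel) -> np.ndarray:
    """Distances between rank-matched centroids of the two rounds."""
    if model_i.k != model_j.k:
        raise ValueError(
            f"cluster counts differ between rounds ({model_i.k} vs {model_j.k}); "
            "use the fixed-K fit"
        )
    return np.linalg.norm(model_i.centroids - model_j.centroids, axis=1)


def build_incremental_vector(
    model_i: ClusterModel, model_j: ClusterModel
) -> IncrementalFeatureVector:
    """Sort both models and concatenate the five blocks."""
    if model_i.k != model_j.k:
        raise ValueError(
            f"cluster counts differ between rounds ({model_i.k} vs {model_j.k})"
        )
    mi = sort_clusters(model_i)
    mj = sort_clusters(model_j)
    values = np.concatenate(
        [
            centroid_distances(mi),
            within_cluster_spread(mi),
            centroid_distances(mj),
            within_cluster_spread(mj),
            cross_round_shift(mi, mj),
        ]
    )
    return IncrementalFeatureVector(values=values, k=mi.k)
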