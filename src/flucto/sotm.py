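"""Self-organizing tree map (SOTM) clustering.

SOTM is an online competitive-learning clusterer: vectors are presented one
at a time in seeded random order; each either updates its nearest node
(learning rate alpha(r)) or, when its distance exceeds the hierarchical
control threshold H(r), seeds a new node.  The thresholds are

    H(r)     = H(0) * (1 - exp(-r / (2N)))
    alpha(r) = alpha0 * exp(-r / tau_eff)

where H(0) is the sum of the per-feature data ranges, N the number of
vectors, and r the presentation counter.  By default tau_eff = tau * N so
the learning rate decays over roughly one data pass; the literal constant
tau (which freezes learning after the first vector) is available via
``literal_tau``.

Two fitting modes are provided: the free fit (``fit_sotm``) stops at MaxItr
presentations or MaxCls nodes and is used to choose a cluster count, while
the fixed-K fit (``fit_sotm_fixed_k``) drops the iteration cap, grows until
exactly K nodes exist and then completes one full convergence pass, so that
every round yields the same number of clusters.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SotmParams",
    "ClusterModel",
    "h_threshold",
    "learning_rate",
    "update_node",
    "fit_sotm",
    "fit_sotm_fixed_k",
    "select_fixed_k",
]


@dataclass(frozen=True)
class SotmParams:
    """SOTM hyperparameters.

    max_itr
        Free-fit presentation cap; None means 10·N.
    max_cls
        Free-fit node-count cap; the default of 5 brackets the cluster
        counts (mean about 4.3) reported for wearable symptom-feature
        rounds of this kind.
    alpha0, tau
        Learning-rate scale (0.8) and decay constant (0.1); the effective
        decay is tau·N presentations unless ``literal_tau``.
    normalize
        Min–max scale features before clustering (off by default; distances
        then weight features by their raw ranges).
    seed
        Seeds the presentation order and root choice.
    """

    max_itr: Optional[int] = None
    max_cls: int = 5
    alpha0: float = 0.8
    tau: float = 0.1
    literal_tau: bool = False
    normalize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_cls < 1:
            raise ValueError("max_cls must be >= 1")
        if not 0 < self.alpha0 <= 1:
            raise ValueError("alpha0 must be in (0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class ClusterModel:
    """SOTM output: K centroids with their member vectors.

    memberships[k] holds the indices (into ``vectors``) assigned to node k
    after the final nearest-centroid re-assignment; creation_order records
    the presentation count at which each node was created (root = 0).
    """

    centroids: np.ndarray  # (K, D)
    memberships: list[np.ndarray]
    creation_order: list[int]
    vectors: np.ndarray  # (N, D), the training data
    params: SotmParams

    @property
    def k(self) -> int:
        return len(self.centroids)

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(m) for m in self.memberships])

    def members(self, k: int) -> np.ndarray:
        return self.vectors[self.memberships[k]]

    def to_json(self) -> str:
        payload = {
            "centroids": self.centroids.tolist(),
            "memberships": [m.tolist() for m in self.memberships],
            "creation_order": list(self.creation_order),
            "vectors": self.vectors.tolist(),
            "params": asdict(self.params),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ClusterModel":
        payload = json.loads(text)
        return cls(
            centroids=np.asarray(payload["centroids"], dtype=float),
            memberships=[np.asarray(m, dtype=int) for m in payload["memberships"]],
            creation_order=list(payload["creation_order"]),
            vectors=np.asarray(payload["vectors"], dtype=float),
            params=SotmParams(**payload["params"]),
        )


def h_threshold(r: int, h0: float, n_vectors: int) -> float:
    """Hierarchical control threshold H(r) = H0·(1 − exp(−r / 2N))."""
    if r < 0:
        raise ValueError("r must be >= 0")
    if n_vectors < 1:
        raise ValueError("n_vectors must be >= 1")
    return h0 * (1.0 - math.exp(-r / (2.0 * n_vectors)))


def learning_rate(r: int, params: SotmParams, n_vectors: int) -> float:
    """alpha(r) = alpha0·exp(−r / tau_eff), strictly decreasing in r."""
    tau_eff = params.tau if params.literal_tau else params.tau * n_vectors
    return params.alpha0 * math.exp(-r / tau_eff)


def update_node(centroid: np.ndarray, f: np.ndarray, alpha: float) -> np.ndarray:
    """Move a centroid toward a vector: C + alpha·(f − C), alpha in [0, 1]."""
    centroid = np.asarray(centroid, dtype=float)
    f = np.asarray(f, dtype=float)
    if centroid.shape != f.shape:
        raise ValueError("centroid and vector dimensions differ")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    return centroid + alpha * (f - centroid)


def _data_range_sum(x: np.ndarray) -> float:
    return float((x.max(axis=0) - x.min(axis=0)).sum())


def _prepare(vectors) -> np.ndarray:
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2 or len(x) == 0:
        raise ValueError("vectors must be a non-empty (N, D) array")
    return x


def _normalize(x: np.ndarray) -> np.ndarray:
    lo = x.min(axis=0)
    rng = x.max(axis=0) - lo
    rng[rng == 0] = 1.0
    return (x - lo) / rng


def _assign(x: np.ndarray, centroids: np.ndarray) -> list[np.ndarray]:
    d = np.linalg.norm(x[:, None, :] - centroids[None, :, :], axis=2)
    nearest = d.argmin(axis=1)
    return [np.flatnonzero(nearest == k) for k in range(len(centroids))]


def _finalize(
    x: np.ndarray, centroids: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Final cluster definition: nearest-node assignment, then each node is
    recentred to the mean of its members.

    The online node positions are single-pass stochastic estimates whose
    variance is set by the learning-rate schedule, not the cluster size;
    reporting each cluster's actual centroid makes the model well-defined
    and presentation-order-insensitive (empty nodes keep their position).
    """
    memberships = _assign(x, centroids)
    centroids = centroids.copy()
    for k, members in enumerate(memberships):
        if len(members):
            centroids[k] = x[members].mean(axis=0)
    return centroids, memberships


class _Presenter:
    """Seeded without-replacement vector presentation, reshuffled per epoch."""

    def __init__(self, n: int, rng: np.random.Generator) -> None:
        self._n = n
        self._rng = rng
        self._order = rng.permutation(n)
        self._pos = 0
        self.epoch_start = True

    def next(self) -> int:
        if self._pos == self._n:
            self._order = self._rng.permutation(self._n)
            self._pos = 0
        self.epoch_start = self._pos == 0
        i = int(self._order[self._pos])
        self._pos += 1
        return i


def fit_sotm(vectors, params: SotmParams = SotmParams()) -> ClusterModel:
    """Free SOTM fit: grow and adapt nodes until MaxItr or MaxCls.

    Deterministic for a given seed.  Final memberships are re-assigned to
    the nearest final centroid so counts and spreads are order-insensitive.
    """
    x_raw = _prepare(vectors)
    x = _normalize(x_raw) if params.normalize else x_raw
    n = len(x)
    h0 = _data_range_sum(x)
    max_itr = params.max_itr if params.max_itr is not None else 10 * n
    rng = np.random.default_rng(params.seed)
    presenter = _Presenter(n, rng)

    centroids = [x[presenter.next()].copy()]
    creation = [0]
    r = 1
    while r <= max_itr and len(centroids) < params.max_cls:
        f = x[presenter.next()]
        cents = np.asarray(centroids)
        dists = np.linalg.norm(cents - f, axis=1)
        k_star = int(dists.argmin())
        if dists[k_star] <= h_threshold(r, h0, n):
            centroids[k_star] = update_node(
                centroids[k_star], f, learning_rate(r, params, n)
            )
        else:
            centroids.append(f.copy())
            creation.append(r)
        r += 1

    cents, memberships = _finalize(x, np.asarray(centroids))
    return ClusterModel(
        centroids=cents,
        memberships=memberships,
        creation_order=creation,
        vectors=x,
        params=params,
    )


def fit_sotm_fixed_k(
    vectors, k: int, params: SotmParams = SotmParams()
) -> ClusterModel:
    """SOTM fit constrained to exactly K nodes.

    The presentation loop cycles through the data (reshuffling each epoch)
    until K nodes exist, then one full convergence pass updates the nodes.
    Because H(r) grows toward H(0), node creation can stall; after any full
    epoch without a creation the vector farthest from its nearest node seeds
    the next node, which keeps the growth phase finite and deterministic.
    """
    x_raw = _prepare(vectors)
    x = _normalize(x_raw) if params.normalize else x_raw
    n = len(x)
    n_distinct = len(np.unique(x, axis=0))
    if n_distinct < k:
        raise ValueError(
            f"need at least {k} distinct vectors for K={k}, got {n_distinct}"
        )
    h0 = _data_range_sum(x)
    rng = np.random.default_rng(params.seed)
    presenter = _Presenter(n, rng)

    centroids = [x[presenter.next()].copy()]
    creation = [0]
    r = 1
    created_this_epoch = True
    while len(centroids) < k:
        i = presenter.next()
        if presenter.epoch_start:
            if not created_this_epoch:
                cents = np.asarray(centroids)
                d = np.linalg.norm(x[:, None, :] - cents[None, :, :], axis=2).min(
                    axis=1
                )
                far = int(d.argmax())
                centroids.append(x[far].copy())
                creation.append(r)
                if len(centroids) == k:
                    break
            created_this_epoch = False
        f = x[i]
        cents = np.asarray(centroids)
        dists = np.linalg.norm(cents - f, axis=1)
        k_star = int(dists.argmin())
        if dists[k_star] <= h_threshold(r, h0, n):
            centroids[k_star] = update_node(
                centroids[k_star], f, learning_rate(r, params, n)
            )
        else:
            centroids.append(f.copy())
            creation.append(r)
            created_this_epoch = True
        r += 1

    # convergence pass: one full epoch of updates, no further creation
    for _ in range(n):
        f = x[presenter.next()]
        cents = np.asarray(centroids)
        dists = np.linalg.norm(cents - f, axis=1)
        k_star = int(dists.argmin())
        centroids[k_star] = update_node(
            centroids[k_star], f, learning_rate(r, params, n)
        )
        r += 1

    cents, memberships = _finalize(x, np.asarray(centroids))
    assert len(cents) == k
    return ClusterModel(
        centroids=cents,
        memberships=memberships,
        creation_order=creation,
        vectors=x,
        params=params,
    )


def select_fixed_k(
    training_rounds: Sequence[np.ndarray], params: SotmParams = SotmParams()
) -> int:
    """Cluster-count selection: median of free-fit counts, rounded half down.

    Each training round's symptom-feature vectors are clustered with the
    free fit; K is the half-down-rounded median of the resulting node
    counts, never below 1.
    """
    if len(training_rounds) == 0:
        raise ValueError("need at least one training round")
    counts = [fit_sotm(v, params).k for v in training_rounds]
    med = float(np.median(counts))
    return max(1, math.ceil(med - 0.5))
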