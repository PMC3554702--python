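"""Gnostic sets: per-(category, channel) banks of unit-norm exemplar units.

Each unit is a weight vector on the unit sphere; its activity on a whitened,
unit-length input is the dot product (cosine similarity), and the set's output
is the max-pooled activity over its units.  Units are learned by spherical
k-means on the category's own whitened training features, with the number of
units growing only polylogarithmically in the amount of training data — a
category seen often is summarized by proportionally fewer exemplars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_UNIT_TOL = 1e-6


@dataclass
class AllocationPolicy:
    """Controls how many exemplar units a gnostic set recruits.

    ``alpha`` scales the polylog allocation curve; ``cap_at_n`` caps the count
    at the number of training vectors (always sensible; kept switchable for
    experiments).
    """

    alpha: float = 10.0
    cap_at_n: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")


@dataclass
class GnosticSet:
    category_id: str
    channel_id: str
    units: np.ndarray  # (n_units, d), rows unit length

    def __post_init__(self) -> None:
        self.units = np.atleast_2d(np.asarray(self.units, dtype=float))
        if self.units.shape[0] < 1:
            raise ValueError("a gnostic set needs at least one unit")
        nrm = np.linalg.norm(self.units, axis=1)
        if np.any(np.abs(nrm - 1.0) > 1e-10):
            raise ValueError("gnostic unit rows must be unit length")

    @property
    def n_units(self) -> int:
        return int(self.units.shape[0])


def allocate_units(n: int, d: int, policy: AllocationPolicy | None = None) -> int:
    """Number of exemplar units for ``n`` training vectors of dimension ``d``.

    min(n, ceil(alpha * log2(n+1)^2 / sqrt(d))), clamped to >= 1.  The count
    is nondecreasing in n while the allocated *fraction* shrinks with
    exposure; with one or two training vectors the set simply stores them.
    """
    if n < 1 or d < 1:
        raise ValueError(f"need n >= 1 and d >= 1, got n={n}, d={d}")
    policy = policy or AllocationPolicy()
    k = math.ceil(policy.alpha * math.log2(n + 1) ** 2 / math.sqrt(d))
    k = max(1, k)
    if policy.cap_at_n:
        k = min(n, k)
    return k


def _validate_unit_points(points: np.ndarray) -> np.ndarray:
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.shape[0] == 0:
        raise ValueError("empty input: no points to cluster")
    nrm = np.linalg.norm(P, axis=1)
    if np.any(np.abs(nrm - 1.0) > _UNIT_TOL):
        raise ValueError("all points must be unit length")
    return P


def _count_distinct(P: np.ndarray) -> int:
    return int(np.unique(np.round(P, 12), axis=0).shape[0])


def spherical_kmeans(
    points: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 100,
) -> np.ndarray:
    """Cluster unit vectors into ``k`` unit-length centroids by cosine similarity.

    Lloyd iterations on the sphere: assign each point to the centroid with the
    largest dot product (ties to the lowest centroid index), then replace each
    centroid with the normalized mean of its points.  Seeding is the cosine
    analogue of k-means++: the first centroid is a uniformly sampled point,
    later ones are sampled with probability proportional to
    max(0, 1 - best cosine so far).  Empty clusters (and clusters whose mean
    cancels to zero) are reseeded from the currently worst-served point.
    The objective, the summed cosine of each point to its centroid, is
    nondecreasing across iterations; the run is deterministic given ``seed``.
    """
    P = _validate_unit_points(points)
    n = P.shape[0]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > _count_distinct(P):
        raise ValueError(f"k={k} exceeds the number of distinct points ({_count_distinct(P)})")

    rng = np.random.default_rng(seed)

    # --- k-means++-style seeding on cosine dissimilarity
    first = int(rng.integers(n))
    centroids = [P[first]]
    best_cos = P @ P[first]
    for _ in range(1, k):
        w = np.clip(1.0 - best_cos, 0.0, None)
        total = w.sum()
        if total > 0:
            idx = int(rng.choice(n, p=w / total))
        else:  # all points coincide with chosen centroids numerically
            idx = int(rng.integers(n))
        centroids.append(P[idx])
        best_cos = np.maximum(best_cos, P @ P[idx])
    C = np.array(centroids)

    assign = np.full(n, -1)
    for _ in range(max_iter):
        S = P @ C.T                       # (n, k) cosine similarities
        new_assign = np.argmax(S, axis=1)  # argmax takes the lowest index on ties
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign

        sums = np.zeros_like(C)
        np.add.at(sums, assign, P)
        counts = np.bincount(assign, minlength=k)
        norms = np.linalg.norm(sums, axis=1)
        worst_order = np.argsort(S.max(axis=1), kind="stable")
        w_i = 0
        for j in range(k):
            if counts[j] > 0 and norms[j] > 0:
                C[j] = sums[j] / norms[j]
            else:  # reseed from the point with the lowest best-cosine
                C[j] = P[worst_order[w_i]]
                w_i += 1
    return C


def kmeans_objective(points: np.ndarray, centroids: np.ndarray) -> float:
    """Sum over points of the cosine to the nearest centroid."""
    P = _validate_unit_points(points)
    C = np.atleast_2d(np.asarray(centroids, dtype=float))
    return float((P @ C.T).max(axis=1).sum())


def fit_gnostic_set(
    category_features: np.ndarray,
    category_id: str,
    channel_id: str,
    policy: AllocationPolicy | None = None,
    seed: int = 0,
) -> GnosticSet:
    """Learn one gnostic set from a single category's whitened unit vectors.

    Only this category's data is used — sets are trained independently, which
    is what lets them act as competing sub-networks rather than as a jointly
    optimized codebook.  The unit count follows :func:`allocate_units`, capped
    at the number of distinct training vectors.
    """
    P = _validate_unit_points(category_features)
    n, d = P.shape
    k = min(allocate_units(n, d, policy), _count_distinct(P))
    units = spherical_kmeans(P, k, seed=seed)
    return GnosticSet(category_id=category_id, channel_id=channel_id, units=units)


def set_response(gset: GnosticSet, x: np.ndarray) -> float:
    """Max-pooled activity of the set on one whitened unit-length input.

    The value lies in [-1, 1]; duplicate units and unit order cannot change it.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (gset.units.shape[1],):
        raise ValueError(
            f"expected a vector of length {gset.units.shape[1]}, got shape {x.shape}"
        )
    return float((gset.units @ x).max())
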