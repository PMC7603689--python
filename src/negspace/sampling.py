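"""Representative negative-subset selection from the closed-world pool.

Three strategies are provided:

* random — simple uniform sampling without replacement;
* kmeans — cluster the (min-max normalized) pool into K groups, K equal to
  the number of positives, and take one randomly chosen member per cluster,
  so every region of the negative space is represented;
* kennard_stone — deterministic uniform (max-min) selection: start from the
  point closest to the data mean, then repeatedly add the point whose minimum
  Euclidean distance to the selected set is largest.

The K-means step runs a seeded Lloyd iteration initialized with k-means++
(best of several restarts by SSE) so that the per-iteration SSE trajectory
and the empty-cluster policy are explicit and inspectable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from .pair_space import PairTable, apply_minmax, fit_minmax


class Method(str, enum.Enum):
    RANDOM = "random"
    KMEANS = "kmeans"
    KENNARD_STONE = "kennard_stone"


@dataclass(frozen=True)
class SamplingResult:
    """Which pool rows were selected, by which method, with diagnostics."""

    method: Method
    seed: int | None
    selected: tuple[int, ...]
    cluster_assignments: tuple[int, ...] | None = None
    selection_order: tuple[int, ...] | None = None
    sse: float | None = None
    sse_history: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be unique")


def _pool_matrix(pool: PairTable | np.ndarray) -> np.ndarray:
    if isinstance(pool, PairTable):
        return pool.vectors
    return np.asarray(pool, dtype=float)


def _normalized(pool: PairTable | np.ndarray) -> np.ndarray:
    """Min-max normalize features to [0, 1] column-wise (fit on the pool)."""
    if isinstance(pool, PairTable):
        return apply_minmax(pool, fit_minmax(pool)).vectors
    X = np.asarray(pool, dtype=float)
    mins, maxs = X.min(axis=0), X.max(axis=0)
    span = np.where(maxs > mins, maxs - mins, 1.0)
    out = (X - mins) / span
    out[:, maxs == mins] = 0.0
    return out


def sample_random(
    pool: PairTable | np.ndarray, n: int, seed: int
) -> SamplingResult:
    """Uniform sample of ``n`` pool rows without replacement."""
    size = len(_pool_matrix(pool))
    if not 1 <= n <= size:
        raise ValueError(f"n={n} outside [1, {size}]")
    rng = np.random.default_rng(seed)
    selected = rng.choice(size, size=n, replace=False)
    return SamplingResult(Method.RANDOM, seed, tuple(int(i) for i in selected))


def _lloyd(
    X: np.ndarray, K: int, rng: np.random.Generator,
    max_iter: int, tol: float,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """One Lloyd run from a k-means++ start; returns (labels, centers, SSE per iteration)."""
    centers, _ = kmeans_plusplus(
        X, K, random_state=int(rng.integers(2**31 - 1))
    )
    history: list[float] = []
    labels = np.zeros(len(X), dtype=int)
    for _ in range(max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        labels = d2.argmin(axis=1)
        sse = float(d2[np.arange(len(X)), labels].sum())
        history.append(sse)
        new_centers = centers.copy()
        point_d2 = d2[np.arange(len(X)), labels].copy()
        for j in range(K):
            members = X[labels == j]
            if len(members):
                new_centers[j] = members.mean(axis=0)
            else:
                # re-seed an empty centroid at the point currently worst-fit
                worst = int(point_d2.argmax())
                new_centers[j] = X[worst]
                point_d2[worst] = 0.0
        if history[-1] > 0 and len(history) > 1:
            if history[-2] - history[-1] <= tol * history[-2]:
                centers = new_centers
                break
        centers = new_centers
    d2 = cdist(X, centers, "sqeuclidean")
    labels = d2.argmin(axis=1)
    history.append(float(d2[np.arange(len(X)), labels].sum()))
    return labels, centers, history


def sample_kmeans(
    pool: PairTable | np.ndarray,
    K: int,
    seed: int,
    n_init: int = 3,
    max_iter: int = 100,
    tol: float = 1e-6,
    max_retries: int = 3,
) -> SamplingResult:
    """Cluster the pool into K groups and pick one random member per cluster.

    Features are min-max normalized internally before clustering, matching the
    preprocessing used for distance-based selection throughout the package.
    The best of ``n_init`` k-means++ restarts by SSE is kept. Should a run
    still end with empty clusters, it is retried with a derived seed up to
    ``max_retries`` times, after which the largest clusters donate extra
    (distinct) members so exactly K rows are returned.
    """
    X = _normalized(pool)
    n_distinct = len(np.unique(X, axis=0))
    if K > n_distinct:
        raise ValueError(
            f"K={K} exceeds the {n_distinct} distinct pool vectors"
        )
    rng = np.random.default_rng(seed)

    best: tuple[np.ndarray, list[float]] | None = None
    for attempt in range(max_retries + 1):
        for _ in range(n_init):
            labels, _, history = _lloyd(X, K, rng, max_iter, tol)
            if best is None or history[-1] < best[1][-1]:
                best = (labels, history)
        if len(np.unique(best[0])) == K:
            break

    labels, history = best
    occupied = np.unique(labels)
    rows_by_cluster = {j: np.flatnonzero(labels == j) for j in occupied}
    selected = [int(rng.choice(rows)) for rows in rows_by_cluster.values()]
    deficit = K - len(selected)
    if deficit > 0:
        # split-largest fallback: draw extra distinct members from the
        # largest clusters
        taken = set(selected)
        for j in sorted(rows_by_cluster, key=lambda j: -len(rows_by_cluster[j])):
            for row in rng.permutation(rows_by_cluster[j]):
                if deficit == 0:
                    break
                if int(row) not in taken:
                    selected.append(int(row))
                    taken.add(int(row))
                    deficit -= 1
            if deficit == 0:
                break
    return SamplingResult(
        Method.KMEANS,
        seed,
        tuple(selected),
        cluster_assignments=tuple(int(j) for j in labels),
        sse=history[-1],
        sse_history=tuple(history),
    )


def sample_kennard_stone(pool: PairTable | np.ndarray, n: int) -> SamplingResult:
    """Deterministic uniform (Kennard-Stone) selection of ``n`` pool rows.

    The first pick is the row closest to the column-wise mean; every later
    pick maximizes the minimum Euclidean distance to the rows already chosen.
    Ties break toward the lowest row index; no randomness is involved.
    """
    X = _normalized(pool)
    size = len(X)
    if not 1 <= n <= size:
        raise ValueError(f"n={n} outside [1, {size}]")
    mean = X.mean(axis=0)
    first = int(np.linalg.norm(X - mean, axis=1).argmin())
    selected = [first]
    min_dist = np.linalg.norm(X - X[first], axis=1)
    min_dist[first] = -np.inf
    while len(selected) < n:
        nxt = int(min_dist.argmax())  # argmax takes the lowest index on ties
        selected.append(nxt)
        dist_new = np.linalg.norm(X - X[nxt], axis=1)
        min_dist = np.minimum(min_dist, dist_new)
        min_dist[nxt] = -np.inf
    return SamplingResult(
        Method.KENNARD_STONE,
        None,
        tuple(selected),
        selection_order=tuple(range(len(selected))),
    )


def sample(
    pool: PairTable | np.ndarray,
    method: Method | str,
    n: int,
    seed: int = 0,
    **kwargs,
) -> SamplingResult:
    """Dispatch to one of the three sampling strategies by name."""
    method = Method(method)
    if method is Method.RANDOM:
        return sample_random(pool, n, seed)
    if method is Method.KMEANS:
        return sample_kmeans(pool, n, seed, **kwargs)
    return sample_kennard_stone(pool, n)
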