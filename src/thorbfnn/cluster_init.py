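"""K-means clustering of training inputs to place RBF centers.

Each basis function is centered at a cluster centroid of the preprocessed
training predictors, so the network's receptive fields sit in regions of
high data density. Lloyd's algorithm is run from k-means++ seeds with
restarts; the best restart by within-cluster sum of squares (inertia) wins.
The per-iteration inertia trace is retained because its monotone decrease is
part of this module's contract, and an explicit empty-cluster rule
guarantees that exactly ``k`` usable centers come out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import kmeans_plusplus

__all__ = ["KMeansResult", "kmeans_fit", "centers_from_kmeans"]


@dataclass
class KMeansResult:
    """Outcome of one K-means fit (best restart).

    ``inertia_trace`` lists the inertia after each Lloyd iteration of the
    winning restart; it is non-increasing.
    """

    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    n_iter: int
    seed: int
    inertia_trace: list[float] = field(default_factory=list)


def _assign(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # squared distances via expansion; (N, k)
    sq = (
        np.sum(X**2, axis=1)[:, None]
        - 2.0 * X @ centroids.T
        + np.sum(centroids**2, axis=1)[None, :]
    )
    np.maximum(sq, 0.0, out=sq)
    labels = np.argmin(sq, axis=1)
    return labels, sq


def _inertia(X, centroids, labels) -> float:
    diff = X - centroids[labels]
    return float(np.sum(diff**2))


def _lloyd(X: np.ndarray, init: np.ndarray, max_iter: int, tol: float):
    n, d = X.shape
    k = init.shape[0]
    centroids = init.copy()
    labels, _ = _assign(X, centroids)
    trace: list[float] = []
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        counts = np.bincount(labels, minlength=k).astype(float)
        new = np.empty_like(centroids)
        for dim in range(d):
            new[:, dim] = np.bincount(labels, weights=X[:, dim], minlength=k)
        nonempty = counts > 0
        new[nonempty] /= counts[nonempty, None]
        if not nonempty.all():
            # empty cluster: seize the point farthest from its centroid
            resid = np.sum((X - centroids[labels]) ** 2, axis=1)
            order = np.argsort(resid)[::-1]
            for pos, j in enumerate(np.flatnonzero(~nonempty)):
                new[j] = X[order[pos % n]]
        shift = float(np.max(np.sqrt(np.sum((new - centroids) ** 2, axis=1))))
        centroids = new
        labels, _ = _assign(X, centroids)
        trace.append(_inertia(X, centroids, labels))
        if shift <= tol:
            break
    return centroids, labels, trace, n_iter


def kmeans_fit(
    X,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    n_init: int = 10,
    tol: float = 1e-6,
) -> KMeansResult:
    """Cluster rows of ``X`` into ``k`` groups minimizing within-cluster SSQ.

    Runs Lloyd's algorithm from ``n_init`` independent k-means++ seedings and
    keeps the restart with the lowest inertia. Deterministic given ``seed``.
    ``k`` larger than the number of points is clamped (with a warning); a
    non-positive ``k`` is an error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n == 0:
        raise ValueError("cannot cluster an empty matrix")
    if k > n:
        import warnings

        warnings.warn(f"k={k} exceeds N={n}; clamping to N", stacklevel=2)
        k = n

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        restart_seed = int(rng.integers(0, 2**31 - 1))
        init, _ = kmeans_plusplus(X, n_clusters=k, random_state=restart_seed)
        centroids, labels, trace, n_iter = _lloyd(X, init, max_iter, tol)
        inertia = trace[-1] if trace else _inertia(X, centroids, labels)
        if best is None or inertia < best[0]:
            best = (inertia, centroids, labels, trace, n_iter)

    inertia, centroids, labels, trace, n_iter = best
    return KMeansResult(
        centroids=centroids,
        assignments=labels.astype(int),
        inertia=inertia,
        n_iter=n_iter,
        seed=seed,
        inertia_trace=trace,
    )


def centers_from_kmeans(result: KMeansResult) -> np.ndarray:
    """Centroids in canonical (lexicographic) row order, for use as RBF centers.

    Sorting by first coordinate, then subsequent ones, makes the center
    matrix independent of the arbitrary cluster numbering produced by a
    particular restart, so downstream training is reproducible.
    """
    c = np.atleast_2d(np.asarray(result.centroids, dtype=float))
    order = np.lexsort(tuple(c[:, j] for j in reversed(range(c.shape[1]))))
    return c[order]
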