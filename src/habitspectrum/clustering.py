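"""k-means habit clustering with explained-variance and elbow selection.

Observations — raw behavioral spectra or five-feature variability vectors —
are clustered with best-of-restarts Lloyd k-means (k-means++ initialisation,
scikit-learn backend).  Cluster quality is scored by the uncentered
explained-variance ratio

    EV = 1 - sum_i ||u_i - c(u_i)||^2 / sum_i ||u_i||^2

which is strictly positive already at k = 1 whenever the data have a nonzero
mean (the centred between/total ratio is identically 0 there); the
conventional centred ratio is available as ``mode="bss_tss"``.  The habit
count is suggested from the explained-variance curve over k = 1..k_max by the
elbow rule: the interior k with the sharpest downward bend (largest negative
discrete second difference), ties resolved to the smallest k.  The full curve
is always returned so a human can override the suggestion.

Variability features span several orders of magnitude (variance ~1e-4 vs
entropy ~5), so they should be z-scored before clustering; see
:func:`standardize_features`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "ClusterModel",
    "ElbowCurve",
    "StandardizeTransform",
    "kmeans_cluster",
    "explained_variance",
    "explained_variance_from_labels",
    "elbow_curve",
    "standardize_features",
]


@dataclass(frozen=True)
class ClusterModel:
    k: int
    centroids: np.ndarray  # (k, n_features)
    assignments: np.ndarray  # (n,) cluster index per observation
    wss: float  # within-cluster sum of squares
    explained_variance: float
    restarts_used: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.explained_variance <= 1.0:
            raise ValueError("explained_variance must lie in [0, 1]")
        if self.wss < 0:
            raise ValueError("wss must be >= 0")
        counts = np.bincount(self.assignments, minlength=self.k)
        if np.any(counts == 0):
            raise ValueError("cluster model contains an empty cluster")


@dataclass(frozen=True)
class ElbowCurve:
    ks: tuple[int, ...]
    explained: tuple[float, ...]
    suggested_k: int
    models: tuple[ClusterModel, ...] = ()

    def __post_init__(self) -> None:
        if list(self.ks) != sorted(set(self.ks)):
            raise ValueError("ks must be strictly increasing")


@dataclass(frozen=True)
class StandardizeTransform:
    """Invertible per-feature z-scoring (zero-variance features map to 0)."""

    mean: np.ndarray
    scale: np.ndarray  # per-feature SD; 0 marks a constant feature

    def apply(self, data: np.ndarray) -> np.ndarray:
        safe = np.where(self.scale == 0, 1.0, self.scale)
        z = (np.asarray(data, float) - self.mean) / safe
        return np.where(self.scale == 0, 0.0, z)

    def invert(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, float) * self.scale + self.mean


def _as_matrix(data: Sequence[Sequence[float]] | np.ndarray) -> np.ndarray:
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.size == 0:
        raise ValueError("data must be a non-empty 2-D array of equal-length vectors")
    return X


def _n_distinct(X: np.ndarray) -> int:
    return np.unique(X, axis=0).shape[0]


def explained_variance_from_labels(
    data: np.ndarray, assignments: np.ndarray, mode: str = "uncentered"
) -> float:
    """Explained-variance ratio of a partition, with per-cluster mean centroids.

    ``"uncentered"``: 1 - WSS / sum ||u_i||^2 (positive at k = 1 for data with
    nonzero mean).  ``"bss_tss"``: the conventional 1 - WSS / TSS about the
    grand mean.  All-zero (resp. constant) data make the denominator 0; the
    ratio is then defined as 1 with a warning.
    """
    X = _as_matrix(data)
    labels = np.asarray(assignments)
    wss = 0.0
    for c in np.unique(labels):
        members = X[labels == c]
        wss += float(np.sum((members - members.mean(axis=0)) ** 2))
    if mode == "uncentered":
        total = float(np.sum(X**2))
    elif mode == "bss_tss":
        total = float(np.sum((X - X.mean(axis=0)) ** 2))
    else:
        raise ValueError("mode must be 'uncentered' or 'bss_tss'")
    if total == 0.0:
        warnings.warn("zero total sum of squares: explained variance set to 1", stacklevel=2)
        return 1.0
    return float(np.clip(1.0 - wss / total, 0.0, 1.0))


def explained_variance(data: np.ndarray, model: ClusterModel, mode: str = "uncentered") -> float:
    """Explained variance of a fitted model on its data (see module docstring)."""
    return explained_variance_from_labels(data, model.assignments, mode=mode)


def _model_from_kmeans(
    X: np.ndarray, km: KMeans, restarts: int, seed: int, ev_mode: str
) -> ClusterModel:
    labels = km.labels_.astype(int)
    return ClusterModel(
        k=km.n_clusters,
        centroids=km.cluster_centers_.copy(),
        assignments=labels,
        wss=float(km.inertia_),
        explained_variance=explained_variance_from_labels(X, labels, mode=ev_mode),
        restarts_used=restarts,
        seed=seed,
    )


def kmeans_cluster(
    data: Sequence[Sequence[float]] | np.ndarray,
    k: int,
    restarts: int = 50,
    max_iter: int = 300,
    seed: int = 0,
    ev_mode: str = "uncentered",
    init: np.ndarray | None = None,
) -> ClusterModel:
    """Best-of-``restarts`` Lloyd k-means, deterministic given ``seed``.

    Among the restarts (k-means++ initialisation) the run with minimal
    within-cluster sum of squares is returned.  ``init`` optionally supplies
    explicit starting centroids for a single extra run, whose solution is
    kept if it beats the random restarts (used for warm-starting the elbow
    sweep).
    """
    X = _as_matrix(data)
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = _n_distinct(X)
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the number of distinct data points ({n_distinct})")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=restarts, max_iter=max_iter, random_state=seed
    ).fit(X)
    best = km
    if init is not None:
        km2 = KMeans(
            n_clusters=k, init=np.asarray(init, float), n_init=1, max_iter=max_iter,
            random_state=seed,
        ).fit(X)
        if km2.inertia_ < best.inertia_ and len(np.unique(km2.labels_)) == k:
            best = km2
    return _model_from_kmeans(X, best, restarts, seed, ev_mode)


def _warm_start_centroids(X: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Previous centroids plus the point farthest from its assigned centroid."""
    dists = np.linalg.norm(X - model.centroids[model.assignments], axis=1)
    far = X[int(np.argmax(dists))]
    return np.vstack([model.centroids, far])


def elbow_curve(
    data: Sequence[Sequence[float]] | np.ndarray,
    k_max: int,
    restarts: int = 50,
    seed: int = 0,
    ev_mode: str = "uncentered",
    keep_models: bool = False,
) -> ElbowCurve:
    """Explained-variance curve for k = 1..k_max with an elbow suggestion.

    Each k is fit best-of-restarts; in addition the k-1 solution, augmented
    with the point farthest from its centroid, seeds one warm-started run, so
    the within-cluster sum of squares can never increase with k and the
    explained curve is non-decreasing.  ``suggested_k`` is the interior k with
    the sharpest bend — the largest value of 2*e[k] - e[k-1] - e[k+1] — with
    ties going to the smallest k.
    """
    X = _as_matrix(data)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > _n_distinct(X):
        raise ValueError("k_max exceeds the number of distinct data points")
    models: list[ClusterModel] = []
    for k in range(1, k_max + 1):
        init = _warm_start_centroids(X, models[-1]) if models else None
        models.append(
            kmeans_cluster(
                X, k, restarts=restarts, seed=seed + k, ev_mode=ev_mode, init=init
            )
        )
    explained = [m.explained_variance for m in models]
    suggested = _suggest_elbow([m.k for m in models], explained)
    return ElbowCurve(
        ks=tuple(m.k for m in models),
        explained=tuple(explained),
        suggested_k=suggested,
        models=tuple(models) if keep_models else (),
    )


def _suggest_elbow(ks: Sequence[int], explained: Sequence[float]) -> int:
    if len(ks) == 1:
        return ks[0]
    if len(ks) == 2:
        return ks[1]
    e = np.asarray(explained, float)
    # downward curvature at interior points; sharpest bend wins, ties -> smallest k
    bend = 2 * e[1:-1] - e[:-2] - e[2:]
    return int(ks[1 + int(np.argmax(bend))])


def standardize_features(
    data: Sequence[Sequence[float]] | np.ndarray,
) -> tuple[np.ndarray, StandardizeTransform]:
    """z-score each feature column; constant columns map to all zeros.

    Requires at least two observations.  Returns the transformed matrix and
    the invertible transform (population SDs).
    """
    X = _as_matrix(data)
    if X.shape[0] < 2:
        raise ValueError("standardization requires at least 2 observations")
    transform = StandardizeTransform(mean=X.mean(axis=0), scale=X.std(axis=0))
    return transform.apply(X), transform
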