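"""K-means++ seeding, Lloyd iterations, and tumor-mask extraction.

The segmenter clusters per-pixel feature vectors — scalar intensity by
default, optionally (intensity, row, col) with coordinates scaled to
[0, 1] — and selects the cluster with the highest centroid intensity as
the tumor.  That selection rule assumes the lesion is hyperintense,
which holds for the phantoms this package generates and for the
T2/FLAIR-like presentations the pipeline targets.

K-means++ draws the first centroid uniformly from the data and every
subsequent centroid with probability proportional to D(x)^2, the squared
Euclidean distance from x to its nearest already-chosen centroid.  Lloyd
iterations then alternate nearest-centroid assignment and centroid-mean
updates until the maximum centroid displacement falls below ``tol``.
Empty clusters are re-seeded at the point farthest from its nearest
centroid, keeping k fixed and the run deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import Image, UNIT

__all__ = [
    "ClusterModel",
    "SegmentationResult",
    "euclidean_distance",
    "kmeanspp_init",
    "kmeans_cluster",
    "segment_tumor",
    "dice",
]

DEFAULT_K = 3  # background / brain tissue / tumor
DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 100


@dataclass(frozen=True)
class ClusterModel:
    k: int
    centroids: np.ndarray          # (k, q)
    labels: np.ndarray             # (n,) ints in [0, k)
    inertia: float                 # sum of squared distances to assigned centroids
    n_iter: int = 0
    inertia_history: tuple = ()    # inertia after each Lloyd iteration

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("non-finite centroid")
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("label outside [0, k)")
        if self.inertia < 0:
            raise ValueError("inertia must be >= 0")


@dataclass(frozen=True)
class SegmentationResult:
    cluster_model: ClusterModel
    tumor_mask: np.ndarray         # binary, image-shaped
    tumor_cluster_index: int


def euclidean_distance(a, b) -> float:
    """Euclidean distance between two points of equal dimension."""
    a = np.atleast_1d(np.asarray(a, dtype=np.float64))
    b = np.atleast_1d(np.asarray(b, dtype=np.float64))
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.ndim != 2 or len(pts) == 0:
        raise ValueError("points must be a nonempty (n, q) array")
    return pts


def _sq_dists_to_nearest(pts: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.min(axis=1)


def kmeanspp_init(points, k: int, seed: int | np.random.Generator = 0,
                  first_index: int | None = None) -> np.ndarray:
    """Draw k initial centroids by the D^2 seeding law.

    Parameters
    ----------
    first_index : int, optional
        Force the index of the first centroid instead of drawing it
        uniformly (useful for deterministic pipelines and for verifying
        the conditional D^2 law).
    """
    pts = _as_points(points)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(np.unique(pts, axis=0)) < k:
        raise ValueError(f"need at least k={k} distinct points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    first = int(rng.integers(len(pts))) if first_index is None else first_index
    centroids = [pts[first]]
    for _ in range(1, k):
        d2 = _sq_dists_to_nearest(pts, np.asarray(centroids))
        total = d2.sum()
        if total == 0:
            raise ValueError("fewer distinct points than k after seeding")
        idx = rng.choice(len(pts), p=d2 / total)
        centroids.append(pts[idx])
    return np.asarray(centroids)


def kmeans_cluster(points, k: int, seed: int = 0, tol: float = DEFAULT_TOL,
                   max_iter: int = DEFAULT_MAX_ITER,
                   n_init: int = 10) -> ClusterModel:
    """K-means++ seeded Lloyd clustering.

    Stops when the maximum centroid displacement is <= ``tol`` or after
    ``max_iter`` iterations.  Inertia is non-increasing across iterations.
    With ``n_init`` > 1 the whole procedure restarts from fresh seeded
    initializations and the run with the lowest converged inertia wins —
    the usual defense against poor local minima of Lloyd's algorithm.
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    if n_init > 1:
        runs = [kmeans_cluster(points, k, seed + 7919 * r, tol, max_iter,
                               n_init=1)
                for r in range(n_init)]
        return min(runs, key=lambda m: m.inertia)
    pts = _as_points(points)
    if k < 1 or max_iter < 1 or tol < 0:
        raise ValueError("need k >= 1, max_iter >= 1, tol >= 0")
    rng = np.random.default_rng(seed)
    centroids = kmeanspp_init(pts, k, rng)

    history: list[float] = []
    labels = np.zeros(len(pts), dtype=np.intp)
    for it in range(1, max_iter + 1):
        d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)

        new_centroids = centroids.copy()
        for j in range(k):
            members = pts[labels == j]
            if len(members):
                new_centroids[j] = members.mean(axis=0)
        # re-seed empty clusters at the point farthest from its nearest centroid
        for j in range(k):
            if not np.any(labels == j):
                far = _sq_dists_to_nearest(pts, new_centroids).argmax()
                new_centroids[j] = pts[far]
                labels[far] = j

        d2 = ((pts[:, None, :] - new_centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(len(pts)), labels].sum())
        history.append(inertia)

        shift = np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max()
        centroids = new_centroids
        if shift <= tol:
            break

    return ClusterModel(k=k, centroids=centroids, labels=labels,
                        inertia=history[-1], n_iter=it,
                        inertia_history=tuple(history))


DEFAULT_N_INIT = 10


def segment_tumor(image: Image, k: int = DEFAULT_K, seed: int = 0,
                  use_coordinates: bool = False, tol: float = DEFAULT_TOL,
                  max_iter: int = DEFAULT_MAX_ITER,
                  n_init: int = DEFAULT_N_INIT) -> SegmentationResult:
    """Cluster pixels and return the brightest cluster as the tumor mask."""
    if image.value_range != UNIT:
        raise ValueError("segment_tumor expects a unit-range image")
    if k < 2:
        raise ValueError("k must be >= 2 to distinguish tumor from background")
    h, w = image.pixels.shape
    intens = image.pixels.reshape(-1, 1)
    if np.ptp(intens) == 0:
        raise ValueError("constant image: no tumor/background contrast to cluster")
    if use_coordinates:
        rr, cc = np.mgrid[0:h, 0:w]
        feats = np.column_stack([intens[:, 0],
                                 rr.ravel() / max(h - 1, 1),
                                 cc.ravel() / max(w - 1, 1)])
    else:
        feats = intens

    model = kmeans_cluster(feats, k, seed=seed, tol=tol, max_iter=max_iter,
                           n_init=n_init)
    tumor_idx = int(model.centroids[:, 0].argmax())
    mask = (model.labels == tumor_idx).reshape(h, w)
    return SegmentationResult(model, mask, tumor_idx)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
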