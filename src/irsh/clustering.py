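"""Common K-means spectral histology segmentation.

Pixels from all images of a cohort are pooled into one matrix and clustered
by a single K-means model, so cluster identities (and false colors) are
directly comparable across samples and groups.  The solver is Lloyd's
algorithm with k-means++ initialization, ``n_init`` seeded restarts (lowest
inertia wins), plain squared Euclidean distance on the EMSC-corrected
absorbance, assignment ties broken toward the lowest cluster id, and empty
clusters re-seeded to the point farthest from its current centroid.  The
pooled matrix is canonicalized by a lexicographic row sort before fitting, so
the fit is insensitive to image order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core_io import LabelMap, SpectralImage, WavenumberAxis, distinct_colors
from .errors import DataError, SpectralRangeError

__all__ = [
    "ClusterModel",
    "pool_pixels",
    "kmeans_fit",
    "assign_labels",
    "common_kmeans",
    "cluster_percentages",
    "abundance_table",
    "match_clusters_to_truth",
]


@dataclass
class ClusterModel:
    """Fitted pooled K-means model."""

    k: int
    centroids: np.ndarray  # k x n_features
    inertia: float
    seed: int
    n_init: int
    color_table: list[tuple[int, int, int]] = field(default_factory=list)
    axis: WavenumberAxis | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.centroids.shape[0] != self.k:
            raise DataError("centroid count != k")
        if self.inertia < 0:
            raise DataError("inertia must be >= 0")
        for i in range(self.k):
            for j in range(i + 1, self.k):
                if np.array_equal(self.centroids[i], self.centroids[j]):
                    raise DataError(f"centroids {i} and {j} coincide")
        if not self.color_table:
            self.color_table = distinct_colors(self.k)


def pool_pixels(
    images: list[SpectralImage],
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack unmasked pixel spectra from all images, with row provenance.

    Returns ``(X, provenance)`` where ``X`` holds one unmasked pixel spectrum
    per row (images in listed order, row-major within an image) and
    ``provenance`` maps each row to ``(image_index, image_id, row, col)``.
    """
    if not images:
        raise DataError("no images to pool")
    axis = images[0].axis
    blocks: list[np.ndarray] = []
    prov: list[tuple[int, str, int, int]] = []
    for idx, img in enumerate(images):
        if img.axis != axis:
            raise SpectralRangeError(f"image {idx} is not on the common axis")
        rr, cc = np.nonzero(img.mask)
        blocks.append(img.cube[rr, cc])
        image_id = img.meta.get("sample_id", str(idx))
        prov.extend((idx, image_id, int(r), int(c)) for r, c in zip(rr, cc))
    X = np.vstack(blocks) if blocks else np.empty((0, axis.n))
    provenance = pd.DataFrame(prov, columns=["image_index", "image_id", "row", "col"])
    return X, provenance


def _dist2(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        - 2.0 * (X @ C.T)
        + np.sum(C * C, axis=1)[None, :]
    )
    return np.maximum(d2, 0.0)


def _kmeanspp(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[int(rng.integers(n))]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total > 0:
            idx = int(rng.choice(n, p=d2 / total))
        else:  # all remaining points coincide with a chosen center
            idx = int(rng.integers(n))
        centers[j] = X[idx]
        d2 = np.minimum(d2, np.sum((X - centers[j]) ** 2, axis=1))
    return centers


def _lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float]:
    n, k = X.shape[0], centers.shape[0]
    prev_inertia = np.inf
    labels = np.zeros(n, dtype=np.int64)
    for _ in range(max_iter):
        d2 = _dist2(X, centers)
        labels = np.argmin(d2, axis=1)  # argmin ties -> lowest id
        point_d2 = d2[np.arange(n), labels]
        # empty-cluster repair: re-seed to the farthest point from its centroid
        for j in np.nonzero(np.bincount(labels, minlength=k) == 0)[0]:
            far = int(np.argmax(point_d2))
            centers[j] = X[far]
            labels[far] = j
            point_d2[far] = 0.0
        inertia = float(point_d2.sum())
        assert inertia <= prev_inertia + 1e-9 * max(1.0, prev_inertia), (
            "Lloyd inertia increased"
        )
        prev_inertia = inertia
        new_centers = np.empty_like(centers)
        for j in range(k):
            new_centers[j] = X[labels == j].mean(axis=0)
        shift = float(np.sqrt(np.sum((new_centers - centers) ** 2, axis=1)).max())
        centers = new_centers
        if shift < tol:
            break
    d2 = _dist2(X, centers)
    labels = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(n), labels].sum())
    return centers, labels, inertia


def kmeans_fit(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterModel:
    """Seeded multi-restart Lloyd K-means; the lowest-inertia restart wins."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise DataError("X must be a 2-D pixel matrix")
    if not np.all(np.isfinite(X)):
        raise DataError("pixel matrix contains non-finite values")
    if X.shape[0] < k:
        raise DataError(f"{X.shape[0]} pixels < k={k}")
    if k < 1 or n_init < 1:
        raise DataError("k and n_init must be >= 1")
    # canonical row order: the fit does not depend on how pixels were pooled
    order = np.lexsort(X.T[::-1])
    Xs = X[order]
    best: tuple[float, np.ndarray] | None = None
    for restart in range(n_init):
        rng = np.random.default_rng([int(seed), 101, restart])
        centers = _kmeanspp(Xs, k, rng)
        centers, _, inertia = _lloyd(Xs, centers, max_iter, tol)
        if best is None or inertia < best[0]:
            best = (inertia, centers)
    inertia, centers = best[0], best[1]
    return ClusterModel(
        k=k, centroids=centers, inertia=inertia, seed=seed, n_init=n_init
    )


def assign_labels(img: SpectralImage, model: ClusterModel) -> LabelMap:
    """Nearest-centroid labels for unmasked pixels; masked pixels get -1."""
    if model.axis is not None and img.axis != model.axis:
        raise SpectralRangeError("image is not on the model axis")
    if img.cube.shape[2] != model.centroids.shape[1]:
        raise SpectralRangeError("image channel count != centroid length")
    labels = np.full(img.shape, -1, dtype=np.int64)
    pixels = img.cube[img.mask]
    if pixels.size:
        labels[img.mask] = np.argmin(_dist2(pixels, model.centroids), axis=1)
    return LabelMap(labels, k=model.k, color_table=list(model.color_table))


def common_kmeans(
    images: list[SpectralImage],
    k: int,
    seed: int = 0,
    n_init: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[ClusterModel, list[LabelMap]]:
    """One K-means over the pooled cohort; shared labels/colors for all images."""
    X, _ = pool_pixels(images)
    model = kmeans_fit(X, k, seed=seed, n_init=n_init, max_iter=max_iter, tol=tol)
    model.axis = images[0].axis
    return model, [assign_labels(img, model) for img in images]


def cluster_percentages(lm: LabelMap) -> np.ndarray:
    """Percent of tissue pixels per cluster (sums to 100)."""
    n_tissue = lm.tissue_count
    if n_tissue == 0:
        raise DataError("label map has no tissue pixels")
    counts = np.bincount(lm.labels[lm.labels >= 0], minlength=lm.k)
    return 100.0 * counts / n_tissue


def abundance_table(
    label_maps: list[LabelMap], image_ids: list[str], groups: list[str]
) -> pd.DataFrame:
    """Long-format table (image_id, group, cluster_id, percent)."""
    if not (len(label_maps) == len(image_ids) == len(groups)):
        raise DataError("label_maps, image_ids and groups must align")
    rows = []
    for lm, image_id, group in zip(label_maps, image_ids, groups):
        for cluster_id, percent in enumerate(cluster_percentages(lm)):
            rows.append((image_id, group, cluster_id, float(percent)))
    return pd.DataFrame(rows, columns=["image_id", "group", "cluster_id", "percent"])


def match_clusters_to_truth(
    lm: LabelMap, truth: LabelMap
) -> tuple[dict[int, int], float]:
    """Optimal one-to-one cluster->truth assignment and pixel agreement.

    Solves the rectangular assignment maximizing the confusion-matrix diagonal
    (Hungarian method); agreement is matched pixels over tissue pixels.
    """
    if lm.labels.shape != truth.labels.shape:
        raise DataError("label map shapes differ")
    both = (lm.labels >= 0) & (truth.labels >= 0)
    n_tissue = int(both.sum())
    if n_tissue == 0:
        raise DataError("no overlapping tissue pixels")
    confusion = np.zeros((lm.k, truth.k), dtype=np.int64)
    np.add.at(confusion, (lm.labels[both], truth.labels[both]), 1)
    rows, cols = linear_sum_assignment(confusion, maximize=True)
    mapping = {int(r): int(c) for r, c in zip(rows, cols)}
    agreement = float(confusion[rows, cols].sum()) / n_tissue
    return mapping, agreement
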