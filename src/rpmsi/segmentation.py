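"""k-means segmentation of projected scores and cluster molecular profiles.

Pixels are clustered by Lloyd's algorithm on their k-dimensional score
columns with Euclidean assignment.  Initialization picks distinct data
columns at random (seeded); the best of ``n_restarts`` runs by inertia is
kept.  If a cluster empties during iteration, its centroid is re-seeded to
the point currently farthest from its own centroid.  Convergence: labels
unchanged, or relative inertia change below 1e-6, capped at 300 iterations.

Per-cluster molecular profiles are recomputed from the *original* spectra by
a single streaming pass, so memory stays bounded by C spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from rpmsi.errors import DomainError
from rpmsi.io import MSIDataset
from rpmsi.projection import ScoreMatrix

# Fixed palette (RGB); cycled if there are more clusters than entries.
PALETTE = np.array([
    [31, 119, 180], [255, 127, 14], [44, 160, 44], [214, 39, 40],
    [148, 103, 189], [140, 86, 75], [227, 119, 194], [127, 127, 127],
    [188, 189, 34], [23, 190, 207],
], dtype=np.uint8)

BACKGROUND_RGB = np.array([0, 0, 0], dtype=np.uint8)


@dataclass(frozen=True)
class SegmentationMap:
    """Per-pixel cluster labels (1..C) with centroids in score space."""

    labels: np.ndarray                # (n,) int, values in 1..C
    n_clusters: int
    centroids: np.ndarray             # (C, k)
    inertia: float
    seed: int
    pixel_order: np.ndarray | None = None   # (n, 2) of (x, y)
    grid_shape: tuple[int, int] | None = None  # (width, height)
    inertia_history: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_pixels(self) -> int:
        return len(self.labels)


def _lloyd_once(data: np.ndarray, n_clusters: int, rng: np.random.Generator,
                max_iter: int = 300, rtol: float = 1e-6):
    """One seeded Lloyd run on (n, k) data; returns labels, centroids, history."""
    n = data.shape[0]
    init_idx = rng.choice(n, size=n_clusters, replace=False)
    centroids = data[init_idx].copy()
    labels = np.full(n, -1, dtype=np.int64)
    history = []
    prev_inertia = np.inf
    for _ in range(max_iter):
        d2 = cdist(data, centroids, metric="sqeuclidean")
        new_labels = np.argmin(d2, axis=1)
        # Re-seed empty clusters with the point farthest from its centroid.
        for c in range(n_clusters):
            if not np.any(new_labels == c):
                farthest = int(np.argmax(d2[np.arange(n), new_labels]))
                new_labels[farthest] = c
                centroids[c] = data[farthest]
                d2[:, c] = cdist(data, centroids[c:c + 1], metric="sqeuclidean")[:, 0]
        inertia = float(d2[np.arange(n), new_labels].sum())
        history.append(inertia)
        converged_labels = np.array_equal(new_labels, labels)
        labels = new_labels
        for c in range(n_clusters):
            members = data[labels == c]
            if len(members):
                centroids[c] = members.mean(axis=0)
        if converged_labels:
            break
        if np.isfinite(prev_inertia) and prev_inertia > 0 \
                and (prev_inertia - inertia) / prev_inertia < rtol:
            break
        prev_inertia = inertia
    # Final assignment so centroids are exactly the member means at return.
    d2 = cdist(data, centroids, metric="sqeuclidean")
    labels = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(n), labels].sum())
    history.append(inertia)
    return labels, centroids, inertia, np.array(history)


def kmeans_segment(scores: ScoreMatrix, n_clusters: int, seed: int,
                   n_restarts: int = 10) -> SegmentationMap:
    """Cluster pixels by k-means on score columns; best of ``n_restarts``."""
    data = scores.scores.T  # (n, k)
    n = data.shape[0]
    if n_clusters < 1:
        raise DomainError(f"n_clusters must be >= 1, got {n_clusters}")
    if n_clusters > n:
        raise DomainError(f"n_clusters={n_clusters} exceeds n_pixels={n}")
    if n_restarts < 1:
        raise DomainError("n_restarts must be >= 1")

    best = None
    for restart in range(n_restarts):
        rng = np.random.default_rng([seed, restart])
        labels, centroids, inertia, history = _lloyd_once(data, n_clusters, rng)
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia, history)
    labels, centroids, inertia, history = best

    grid_shape = None
    if scores.pixel_order is not None:
        grid_shape = (int(scores.pixel_order[:, 0].max()),
                      int(scores.pixel_order[:, 1].max()))
    return SegmentationMap(labels=labels + 1, n_clusters=n_clusters,
                           centroids=centroids, inertia=inertia, seed=seed,
                           pixel_order=scores.pixel_order, grid_shape=grid_shape,
                           inertia_history=history)


def label_grid(seg: SegmentationMap) -> np.ndarray:
    """(height, width) integer grid of labels; 0 marks missing pixels."""
    if seg.pixel_order is None or seg.grid_shape is None:
        raise DomainError("segmentation map carries no pixel coordinates")
    width, height = seg.grid_shape
    xs, ys = seg.pixel_order[:, 0], seg.pixel_order[:, 1]
    if xs.min() < 1 or ys.min() < 1 or xs.max() > width or ys.max() > height:
        raise DomainError("pixel coordinate outside the declared grid")
    grid = np.zeros((height, width), dtype=np.int64)
    grid[ys - 1, xs - 1] = seg.labels
    return grid


def render_map(seg: SegmentationMap) -> np.ndarray:
    """(height, width, 3) uint8 RGB image, one fixed palette color per label.

    Pixels absent from the acquisition are rendered as the background color.
    """
    grid = label_grid(seg)
    img = np.empty(grid.shape + (3,), dtype=np.uint8)
    img[:] = BACKGROUND_RGB
    for label in range(1, seg.n_clusters + 1):
        img[grid == label] = PALETTE[(label - 1) % len(PALETTE)]
    return img


def centroid_distance_matrix(seg: SegmentationMap) -> np.ndarray:
    """Symmetric C-by-C Euclidean distances between centroids in score space."""
    if seg.n_clusters < 1:
        raise DomainError("need at least one cluster")
    d = cdist(seg.centroids, seg.centroids, metric="euclidean")
    np.fill_diagonal(d, 0.0)
    return d


@dataclass(frozen=True)
class ClusterProfiles:
    """Mean original spectrum and pixel count per cluster."""

    mean_spectra: np.ndarray   # (C, m) on the dataset's m/z axis
    member_counts: np.ndarray  # (C,)
    mz_axis: np.ndarray


def cluster_mean_spectra(reader: MSIDataset, seg: SegmentationMap) -> ClusterProfiles:
    """Per-cluster mean spectra from the original data, in one streaming pass."""
    if reader.n_pixels != seg.n_pixels:
        raise DomainError(
            f"label count {seg.n_pixels} does not match dataset pixels {reader.n_pixels}")
    c = seg.n_clusters
    sums = np.zeros((c, reader.n_channels), dtype=np.float64)
    counts = np.zeros(c, dtype=np.int64)
    for j, (coord, x) in enumerate(reader.iter_spectra()):
        if seg.pixel_order is not None and not np.array_equal(seg.pixel_order[j], coord):
            raise DomainError(
                f"pixel order mismatch at index {j}: map has "
                f"{tuple(seg.pixel_order[j])}, reader yields {coord}")
        label = seg.labels[j] - 1
        sums[label] += x
        counts[label] += 1
    means = sums / np.maximum(counts, 1)[:, None]
    return ClusterProfiles(mean_spectra=means, member_counts=counts,
                           mz_axis=reader.mz_axis)
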