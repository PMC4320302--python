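"""Reproducibility of segmentations, PCA baseline, and peak-pick diagnostics.

"Correlation between maps" is undefined for categorical labels, so agreement
between two segmentations is measured on their co-assignment structure: for
a (seeded) sample of pixel pairs, each map yields a boolean vector marking
pairs assigned to the same cluster, and the Pearson correlation between the
two vectors is the agreement.  This is invariant to label permutation.  The
adjusted Rand index is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.linalg import eigsh
from sklearn.metrics import adjusted_rand_score

from rpmsi.errors import DomainError
from rpmsi.io import MSIDataset
from rpmsi.projection import ScoreMatrix, make_basis, project_dataset
from rpmsi.segmentation import SegmentationMap, kmeans_segment

#: Pair budget above which pixel pairs are subsampled.
ALL_PAIRS_LIMIT = 2000
DEFAULT_MAX_PAIRS = 1_000_000


def _pair_indices(n: int, seed: int, max_pairs: int) -> tuple[np.ndarray, np.ndarray]:
    if n <= ALL_PAIRS_LIMIT:
        return np.triu_indices(n, k=1)
    rng = np.random.default_rng([seed, n])
    i = rng.integers(0, n, size=2 * max_pairs)
    j = rng.integers(0, n, size=2 * max_pairs)
    keep = i != j
    return i[keep][:max_pairs], j[keep][:max_pairs]


def _coassignment_correlation(labels_a: np.ndarray, labels_b: np.ndarray,
                              i: np.ndarray, j: np.ndarray) -> float:
    sa = (labels_a[i] == labels_a[j]).astype(np.float64)
    sb = (labels_b[i] == labels_b[j]).astype(np.float64)
    va, vb = sa.std(), sb.std()
    if va == 0.0 or vb == 0.0:
        # Degenerate co-assignment structure (e.g. single cluster).
        return 1.0 if np.array_equal(sa, sb) else 0.0
    return float(np.corrcoef(sa, sb)[0, 1])


def segmentation_agreement(map_a: SegmentationMap, map_b: SegmentationMap,
                           seed: int = 0,
                           max_pairs: int = DEFAULT_MAX_PAIRS) -> float:
    """Label-permutation-invariant agreement between two maps, in [-1, 1].

    Pearson correlation of the co-assignment indicators over a common seeded
    sample of pixel pairs (all pairs when n <= 2000).
    """
    if map_a.n_pixels != map_b.n_pixels:
        raise DomainError(
            f"pixel count mismatch: {map_a.n_pixels} vs {map_b.n_pixels}")
    i, j = _pair_indices(map_a.n_pixels, seed, max_pairs)
    return _coassignment_correlation(map_a.labels, map_b.labels, i, j)


def agreement_metrics(map_a: SegmentationMap, map_b: SegmentationMap,
                      seed: int = 0,
                      max_pairs: int = DEFAULT_MAX_PAIRS) -> dict[str, float]:
    """Co-assignment correlation plus adjusted Rand index."""
    corr = segmentation_agreement(map_a, map_b, seed=seed, max_pairs=max_pairs)
    ari = float(adjusted_rand_score(map_a.labels, map_b.labels))
    return {"correlation": corr, "ari": ari}


@dataclass(frozen=True)
class StabilityTable:
    """Pairwise map agreements per projection count, with summaries."""

    pairs: pd.DataFrame    # columns: n_projections, rep_i, rep_j, correlation, ari
    summary: pd.DataFrame  # columns: n_projections, mean_correlation, sd_correlation, mean_ari


def _derived_seed(*parts: int) -> int:
    ss = np.random.SeedSequence(list(parts))
    return int(ss.generate_state(1, dtype=np.uint64)[0] >> 1)


def stability_experiment(reader: MSIDataset, projection_counts, repeats: int,
                         n_clusters: int, seed: int,
                         n_restarts: int = 5) -> StabilityTable:
    """Reproducibility of segmentation across independent random bases.

    For each projection count, ``repeats`` independent bases are drawn,
    projected and segmented; all pairwise agreements between the resulting
    maps are recorded.  Deterministic given ``seed``.
    """
    if repeats < 2:
        raise DomainError("repeats must be >= 2")
    counts = [int(c) for c in projection_counts]
    rows = []
    for count in counts:
        maps = []
        for rep in range(repeats):
            basis = make_basis(count, reader.n_channels,
                               seed=_derived_seed(seed, count, rep))
            scores = project_dataset(reader, basis)
            seg = kmeans_segment(scores, n_clusters,
                                 seed=_derived_seed(seed, count, rep, 1),
                                 n_restarts=n_restarts)
            maps.append(seg)
        for i in range(repeats):
            for j in range(i + 1, repeats):
                met = agreement_metrics(maps[i], maps[j], seed=seed)
                rows.append({"n_projections": count, "rep_i": i, "rep_j": j,
                             "correlation": met["correlation"], "ari": met["ari"]})
    pairs = pd.DataFrame(rows)
    summary = (pairs.groupby("n_projections")
               .agg(mean_correlation=("correlation", "mean"),
                    sd_correlation=("correlation", "std"),
                    mean_ari=("ari", "mean"))
               .reset_index())
    return StabilityTable(pairs=pairs, summary=summary)


def pca_scores(reader: MSIDataset, n_components: int,
               chunk_size: int = 256) -> ScoreMatrix:
    """Scores of pixels on the top principal components of mean-centered data.

    Streaming, three passes: (1) mean spectrum, (2) accumulation of the
    m-by-m scatter of centered spectra in chunks, (3) projection onto the
    leading eigenvectors.  Memory is O(m^2), so this is intended for binned
    axes (thousands of channels), not raw profile data.
    """
    m, n = reader.n_channels, reader.n_pixels
    if n_components < 1 or n_components > min(m, n):
        raise DomainError(
            f"n_components must be in [1, min(m, n)={min(m, n)}], got {n_components}")

    mean = reader.mean_spectrum()

    scatter = np.zeros((m, m), dtype=np.float64)
    buf = np.empty((chunk_size, m), dtype=np.float64)
    fill = 0
    for _, x in reader.iter_spectra():
        buf[fill] = x - mean
        fill += 1
        if fill == chunk_size:
            scatter += buf.T @ buf
            fill = 0
    if fill:
        scatter += buf[:fill].T @ buf[:fill]

    if n_components < m:
        # Fixed start vector keeps the Lanczos iteration deterministic.
        v0 = np.full(m, 1.0 / np.sqrt(m))
        eigvals, eigvecs = eigsh(scatter, k=n_components, which="LA", v0=v0)
        order = np.argsort(eigvals)[::-1]
        components = eigvecs[:, order]
    else:
        eigvals, eigvecs = np.linalg.eigh(scatter)
        components = eigvecs[:, ::-1][:, :n_components]
    # Deterministic sign: largest-magnitude loading positive per component.
    for c in range(components.shape[1]):
        pivot = np.argmax(np.abs(components[:, c]))
        if components[pivot, c] < 0:
            components[:, c] = -components[:, c]

    scores = np.empty((n_components, n), dtype=np.float64)
    order_xy = np.empty((n, 2), dtype=np.int64)
    for jdx, (coord, x) in enumerate(reader.iter_spectra()):
        scores[:, jdx] = components.T @ (x - mean)
        order_xy[jdx] = coord
    meta = {"kind": "pca", "n_components": n_components, "m": m}
    return ScoreMatrix(scores=scores, basis_meta=meta, pixel_order=order_xy)


@dataclass(frozen=True)
class PeakList:
    """Detected peaks: intensity-weighted centroids with apex intensities."""

    centroids: np.ndarray       # strictly increasing m/z values
    apex_intensity: np.ndarray
    window: int                 # full window width in channels (odd)

    def __len__(self) -> int:
        return len(self.centroids)


def peak_pick_max_window(spectrum: np.ndarray, mz_axis: np.ndarray,
                         window: int, min_intensity: float) -> PeakList:
    """Maximum-window peak detection on one spectrum.

    Channel i is a peak iff its intensity is the strict maximum over the
    window of ``window`` channels centered on i (truncated at the spectrum
    edges) and at least ``min_intensity``.  The reported centroid is the
    intensity-weighted mean m/z over the window.
    """
    if window < 1 or window % 2 == 0:
        raise DomainError(f"window must be a positive odd channel count, got {window}")
    spectrum = np.asarray(spectrum, dtype=np.float64)
    mz_axis = np.asarray(mz_axis, dtype=np.float64)
    if spectrum.shape != mz_axis.shape:
        raise DomainError("spectrum and mz_axis must have equal length")
    half = window // 2
    m = len(spectrum)
    centroids, apexes = [], []
    for i in range(m):
        v = spectrum[i]
        if v < min_intensity:
            continue
        lo, hi = max(0, i - half), min(m, i + half + 1)
        win = spectrum[lo:hi]
        others = np.delete(win, i - lo)
        if len(others) == 0 or v > others.max():
            total = win.sum()
            centroid = float((mz_axis[lo:hi] * win).sum() / total) if total > 0 \
                else float(mz_axis[i])
            centroids.append(centroid)
            apexes.append(float(v))
    return PeakList(centroids=np.array(centroids),
                    apex_intensity=np.array(apexes), window=window)
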