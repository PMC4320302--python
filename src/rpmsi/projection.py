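"""Gaussian random projection of spectra: basis generation and scoring.

A basis is a k-by-m matrix of i.i.d. standard-normal draws; each pixel
spectrum x (length m) is reduced to k scores by the matrix-vector product.
Datasets are projected one spectrum at a time so the full m-by-n matrix is
never resident.

Rows of the basis are generated independently from a seed chained with the
row index, so extending a basis by appending rows preserves the existing
rows bit-exactly (prefix property) and extension is associative.  No 1/sqrt(k)
scaling is applied to the stored scores; distance-preservation checks apply
that factor externally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from rpmsi.errors import DomainError
from rpmsi.io import MSIDataset

#: Identifier of the row-wise seeding scheme; bump if the draw order changes.
GENERATOR_ID = "numpy-philox-rowwise-v1"


def _check_seed(seed: int) -> int:
    seed = int(seed)
    if seed < 0:
        raise DomainError("seed must be a non-negative integer")
    return seed


def _basis_row(seed: int, row: int, m: int) -> np.ndarray:
    """Standard-normal row `row` of the basis for (seed, m).

    Each row has its own deterministic stream keyed by (seed, row), which is
    what makes prefix-preserving extension possible.
    """
    rng = np.random.Generator(
        np.random.Philox(key=np.array([seed, row], dtype=np.uint64)))
    return rng.standard_normal(m)


@dataclass(frozen=True)
class ProjectionBasis:
    """A k-by-m Gaussian projection basis with its RNG provenance."""

    matrix: np.ndarray
    seed: int
    generator_id: str = GENERATOR_ID

    @property
    def k(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class ScoreMatrix:
    """The k-by-n matrix of projected scores, one column per pixel.

    ``basis_meta`` records (k, m, seed, generator_id) of the producing basis
    (or the PCA provenance tag); ``pixel_order`` is the (n, 2) array of
    (x, y) coordinates in column order.
    """

    scores: np.ndarray
    basis_meta: dict = field(default_factory=dict)
    pixel_order: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.scores.shape[0]

    @property
    def n(self) -> int:
        return self.scores.shape[1]

    def save(self, path: str | Path) -> Path:
        """Persist as an uncompressed .npz with embedded JSON metadata."""
        path = Path(path)
        meta = json.dumps(self.basis_meta, sort_keys=True)
        pixel_order = self.pixel_order if self.pixel_order is not None \
            else np.zeros((0, 2), dtype=np.int64)
        np.savez(path, scores=self.scores, pixel_order=pixel_order,
                 basis_meta=np.array(meta))
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "ScoreMatrix":
        with np.load(path, allow_pickle=False) as z:
            scores = z["scores"]
            pixel_order = z["pixel_order"]
            meta = json.loads(str(z["basis_meta"]))
        if pixel_order.size == 0:
            pixel_order = None
        return cls(scores=scores, basis_meta=meta, pixel_order=pixel_order)

    def to_tsv(self, path: str | Path) -> Path:
        """Export as delimited text, one row per pixel, one column per projection."""
        path = Path(path)
        header = "x\ty\t" + "\t".join(f"proj_{i + 1}" for i in range(self.k))
        coords = self.pixel_order if self.pixel_order is not None \
            else np.zeros((self.n, 2), dtype=np.int64)
        body = np.column_stack([coords.astype(np.float64), self.scores.T])
        np.savetxt(path, body, delimiter="\t", header=header, comments="",
                   fmt=["%d", "%d"] + ["%.17g"] * self.k)
        return path


def make_basis(k: int, m: int, seed: int) -> ProjectionBasis:
    """Generate a k-by-m standard-normal basis, deterministic given seed."""
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    if m < 1:
        raise DomainError(f"m must be >= 1, got {m}")
    seed = _check_seed(seed)
    matrix = np.empty((k, m), dtype=np.float64)
    for i in range(k):
        matrix[i] = _basis_row(seed, i, m)
    return ProjectionBasis(matrix=matrix, seed=seed)


def extend_basis(basis: ProjectionBasis, k_extra: int) -> ProjectionBasis:
    """Append ``k_extra`` fresh rows; the first k rows are bit-identical.

    Equivalent to ``make_basis(k + k_extra, m, seed)`` because rows are keyed
    by index, so extension is associative.
    """
    if k_extra < 1:
        raise DomainError(f"k_extra must be >= 1, got {k_extra}")
    extra = np.empty((k_extra, basis.m), dtype=np.float64)
    for i in range(k_extra):
        extra[i] = _basis_row(basis.seed, basis.k + i, basis.m)
    return ProjectionBasis(matrix=np.vstack([basis.matrix, extra]),
                           seed=basis.seed, generator_id=basis.generator_id)


def project_spectrum(basis: ProjectionBasis, x: np.ndarray) -> np.ndarray:
    """Project one spectrum onto the basis: score_i = row_i . x."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or len(x) != basis.m:
        raise DomainError(
            f"spectrum length {x.shape} does not match basis m={basis.m}")
    return basis.matrix @ x


def project_dataset(reader: MSIDataset, basis: ProjectionBasis) -> ScoreMatrix:
    """Stream a dataset through the basis, one spectrum at a time.

    Peak resident memory is one spectrum plus the basis plus the scores; the
    m-by-n data matrix is never materialized.
    """
    if reader.n_channels != basis.m:
        raise DomainError(
            f"dataset has {reader.n_channels} channels but basis expects m={basis.m}")
    n = reader.n_pixels
    scores = np.empty((basis.k, n), dtype=np.float64)
    order = np.empty((n, 2), dtype=np.int64)
    for j, (coord, x) in enumerate(reader.iter_spectra()):
        scores[:, j] = basis.matrix @ x
        order[j] = coord
    meta = {"kind": "random_projection", "k": basis.k, "m": basis.m,
            "seed": basis.seed, "generator_id": basis.generator_id}
    return ScoreMatrix(scores=scores, basis_meta=meta, pixel_order=order)
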