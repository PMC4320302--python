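"""Synthetic MSI phantoms with known region structure and spectral profiles.

A phantom is a rectangular grid partitioned into labeled regions by a named
layout; each region owns a multi-peak spectral profile (sums of Gaussian
peak shapes on a shared m/z axis), on top of shared background/matrix peaks
present everywhere.  Noise is additive Gaussian plus a per-pixel
multiplicative gain jitter, and intensities are clamped at zero.  Everything
is deterministic given the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from rpmsi.errors import DomainError
from rpmsi.io import InMemoryMSI

Peak = tuple[float, float, float]  # (center m/z, amplitude, width in Daltons)

LAYOUTS = ("stripes", "nested_blobs", "voronoi")


@dataclass(frozen=True)
class RegionSpec:
    """One tissue class: a name plus its peak profile."""

    name: str
    profile: tuple[Peak, ...] = ()


@dataclass(frozen=True)
class PhantomSpec:
    grid: tuple[int, int]                   # (width, height)
    regions: tuple[RegionSpec, ...]
    shared_peaks: tuple[Peak, ...]
    noise: tuple[float, float]              # (additive SD, multiplicative gain SD)
    mz_range: tuple[float, float]
    n_channels: int
    seed: int
    layout: str = "nested_blobs"

    def validate(self) -> None:
        problems = []
        w, h = self.grid
        if w < 1 or h < 1:
            problems.append(f"grid must be positive, got {self.grid}")
        if not self.regions:
            problems.append("at least one region is required")
        if self.layout not in LAYOUTS:
            problems.append(f"unknown layout {self.layout!r}; expected one of {LAYOUTS}")
        lo, hi = self.mz_range
        if not lo < hi:
            problems.append(f"mz_range must be increasing, got {self.mz_range}")
        for region in self.regions:
            for center, amp, width in region.profile:
                if not (lo <= center <= hi):
                    problems.append(f"peak center {center} outside mz_range in {region.name}")
                if amp <= 0:
                    problems.append(f"non-positive amplitude {amp} in {region.name}")
                if width <= 0:
                    problems.append(f"non-positive width {width} in {region.name}")
        for center, amp, width in self.shared_peaks:
            if not (lo <= center <= hi):
                problems.append(f"shared peak center {center} outside mz_range")
            if amp <= 0 or width <= 0:
                problems.append("shared peaks need positive amplitude and width")
        if self.n_channels < 2:
            problems.append("n_channels must be >= 2")
        if any(s < 0 for s in self.noise):
            problems.append("noise SDs must be non-negative")
        if problems:
            raise DomainError("invalid phantom spec: " + "; ".join(problems))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        raw = json.loads(Path(path).read_text())
        raw["regions"] = tuple(
            RegionSpec(name=r["name"], profile=tuple(tuple(p) for p in r["profile"]))
            for r in raw["regions"])
        raw["shared_peaks"] = tuple(tuple(p) for p in raw["shared_peaks"])
        for key in ("grid", "noise", "mz_range"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Region layouts: each returns an (h, w) int array with values 1..n_regions
# that partitions the grid.
# ---------------------------------------------------------------------------

def _layout_stripes(w: int, h: int, n_regions: int, rng) -> np.ndarray:
    rows = np.minimum(np.arange(h) * n_regions // h, n_regions - 1)
    return np.repeat(rows[:, None] + 1, w, axis=1)


def _layout_voronoi(w: int, h: int, n_regions: int, rng) -> np.ndarray:
    sites = np.column_stack([rng.uniform(0, w, n_regions),
                             rng.uniform(0, h, n_regions)])
    ys, xs = np.mgrid[0:h, 0:w]
    d2 = (xs[..., None] - sites[:, 0]) ** 2 + (ys[..., None] - sites[:, 1]) ** 2
    return np.argmin(d2, axis=-1) + 1


def _layout_nested_blobs(w: int, h: int, n_regions: int, rng) -> np.ndarray:
    """Border frame = region 1, base field = region 2, seeded circular blobs
    = region 3, smaller concentric cores = region 4 (when present)."""
    labels = np.full((h, w), 2 if n_regions >= 2 else 1, dtype=np.int64)
    frame = max(1, min(w, h) // 10)
    labels[:frame, :] = 1
    labels[-frame:, :] = 1
    labels[:, :frame] = 1
    labels[:, -frame:] = 1
    if n_regions < 3:
        return labels
    ys, xs = np.mgrid[0:h, 0:w]
    n_blobs = 5
    radius = max(3.0, min(w, h) / 7.0)
    centers = np.column_stack([
        rng.uniform(frame + radius, w - frame - radius, n_blobs),
        rng.uniform(frame + radius, h - frame - radius, n_blobs)])
    for cx, cy in centers:
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        blob = (d2 <= radius ** 2) & (labels == 2)
        labels[blob] = 3
        if n_regions >= 4:
            core = (d2 <= (radius / 2.0) ** 2) & (labels == 3)
            labels[core] = 4
    return labels


_LAYOUT_FUNCS = {"stripes": _layout_stripes, "voronoi": _layout_voronoi,
                 "nested_blobs": _layout_nested_blobs}


def region_masks(spec: PhantomSpec) -> np.ndarray:
    """Deterministic (h, w) label image (values 1..len(regions))."""
    w, h = spec.grid
    rng = np.random.default_rng([spec.seed, 9001])
    labels = _LAYOUT_FUNCS[spec.layout](w, h, len(spec.regions), rng)
    present = np.unique(labels)
    if not np.array_equal(present, np.arange(1, len(spec.regions) + 1)):
        raise DomainError(
            f"layout {spec.layout!r} produced regions {present.tolist()} for "
            f"{len(spec.regions)} region specs; masks must partition the grid")
    return labels


def _template(profile: Sequence[Peak], shared: Sequence[Peak],
              mz: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mz)
    for center, amp, width in tuple(profile) + tuple(shared):
        out += amp * np.exp(-0.5 * ((mz - center) / width) ** 2)
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[InMemoryMSI, np.ndarray]:
    """Build the dataset and its ground-truth label image.

    Each pixel's spectrum is its region template scaled by a per-pixel gain
    ``1 + N(0, mult_sd)`` plus channel-wise ``N(0, add_sd)`` noise, clamped
    at zero.  Pixels are generated in ascending (y, x) order so the draw
    sequence (and hence the dataset) is reproducible bit-exactly.
    """
    spec.validate()
    w, h = spec.grid
    mz = np.linspace(spec.mz_range[0], spec.mz_range[1], spec.n_channels)
    labels = region_masks(spec)
    templates = np.stack([_template(r.profile, spec.shared_peaks, mz)
                          for r in spec.regions])
    add_sd, mult_sd = spec.noise

    rng = np.random.default_rng([spec.seed, 17])
    n = w * h
    coords = np.empty((n, 2), dtype=np.int64)
    intensities = np.empty((n, spec.n_channels), dtype=np.float64)
    idx = 0
    for y in range(1, h + 1):
        for x in range(1, w + 1):
            template = templates[labels[y - 1, x - 1] - 1]
            gain = 1.0 + rng.normal(0.0, mult_sd) if mult_sd > 0 else 1.0
            noise = rng.normal(0.0, add_sd, spec.n_channels) if add_sd > 0 else 0.0
            coords[idx] = (x, y)
            intensities[idx] = np.clip(template * gain + noise, 0.0, None)
            idx += 1
    return InMemoryMSI(coords, mz, intensities), labels


def _peak_comb(rng, n_peaks: int, lo: float, hi: float,
               amp_range=(20.0, 100.0), width_range=(0.15, 0.4)) -> list[Peak]:
    centers = np.sort(rng.uniform(lo + 5, hi - 5, n_peaks))
    amps = rng.uniform(*amp_range, n_peaks)
    widths = rng.uniform(*width_range, n_peaks)
    return [(float(c), float(a), float(wd)) for c, a, wd in zip(centers, amps, widths)]


def default_liver_like_spec(seed: int = 0) -> PhantomSpec:
    """A 64x64, 4-region phantom emulating a lipid-range tissue image.

    m/z axis spans 600-950 over 4000 channels.  Region 1 (border frame)
    carries only the shared matrix peaks; regions 2-4 each have ~40 peaks,
    with regions 3 and 4 (blobs and their cores) sharing most peak positions
    at different amplitudes so they are the most spectrally similar pair by
    construction.  The additive noise level is tuned so that a handful of
    projections yields unstable segmentations while ~100+ projections
    recover the regions essentially perfectly.
    """
    rng = np.random.default_rng([seed, 4242])
    lo, hi = 600.0, 950.0
    shared = _peak_comb(rng, 8, lo, hi, amp_range=(30.0, 80.0))
    profile_a = _peak_comb(rng, 40, lo, hi)
    blob_peaks = _peak_comb(rng, 40, lo, hi)
    # Cores share 30 of the blobs' 40 peaks, rescaled, plus 10 of their own.
    scale = rng.uniform(0.5, 1.6, 30)
    core_peaks = [(c, float(a * s), wd)
                  for (c, a, wd), s in zip(blob_peaks[:30], scale)]
    core_peaks += _peak_comb(rng, 10, lo, hi)
    core_peaks.sort(key=lambda p: p[0])
    return PhantomSpec(
        grid=(64, 64),
        regions=(
            RegionSpec("matrix_frame", ()),
            RegionSpec("parenchyma", tuple(profile_a)),
            RegionSpec("blobs", tuple(blob_peaks)),
            RegionSpec("blob_cores", tuple(core_peaks)),
        ),
        shared_peaks=tuple(shared),
        noise=(20.0, 0.05),
        mz_range=(lo, hi),
        n_channels=4000,
        seed=seed,
        layout="nested_blobs",
    )


def with_profile_contrast(spec: PhantomSpec, alpha: float) -> PhantomSpec:
    """Scale inter-region profile differences toward their common mean.

    ``alpha=1`` leaves the spec unchanged; ``alpha=0`` gives every region the
    average profile (regions become indistinguishable up to noise).  Used to
    probe downstream failure modes.
    """
    if not 0.0 <= alpha <= 1.0:
        raise DomainError("alpha must lie in [0, 1]")
    all_peaks: dict[tuple[float, float], list[float]] = {}
    for region in spec.regions:
        for center, amp, width in region.profile:
            all_peaks.setdefault((center, width), []).append(amp)
    n_regions = len(spec.regions)
    mean_amp = {key: sum(amps) / n_regions for key, amps in all_peaks.items()}
    new_regions = []
    for region in spec.regions:
        own = {(c, wd): a for c, a, wd in region.profile}
        peaks = []
        for (center, width), mamp in sorted(mean_amp.items()):
            amp = own.get((center, width), 0.0)
            blended = alpha * amp + (1.0 - alpha) * mamp
            if blended > 0:
                peaks.append((center, blended, width))
        new_regions.append(RegionSpec(region.name, tuple(peaks)))
    return PhantomSpec(grid=spec.grid, regions=tuple(new_regions),
                       shared_peaks=spec.shared_peaks, noise=spec.noise,
                       mz_range=spec.mz_range, n_channels=spec.n_channels,
                       seed=spec.seed, layout=spec.layout)
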