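"""Shared fixtures: phantoms at two scales and temporary imzML files."""

from __future__ import annotations

import numpy as np
import pytest

from rpmsi.io import InMemoryMSI, write_imzml
from rpmsi.phantom import (
    PhantomSpec,
    RegionSpec,
    default_liver_like_spec,
    generate_phantom,
)


def small_spec(seed: int = 0, grid=(16, 16), n_channels: int = 400,
               noise=(2.0, 0.02), layout: str = "nested_blobs") -> PhantomSpec:
    """A fast 4-region phantom for unit tests (sub-second generation)."""
    lo, hi = 600.0, 950.0
    rng = np.random.default_rng([seed, 77])

    def comb(n):
        centers = np.sort(rng.uniform(lo + 10, hi - 10, n))
        amps = rng.uniform(30.0, 90.0, n)
        widths = rng.uniform(0.8, 2.0, n)
        return tuple((float(c), float(a), float(w))
                     for c, a, w in zip(centers, amps, widths))

    return PhantomSpec(
        grid=grid,
        regions=(RegionSpec("frame", ()),
                 RegionSpec("field", comb(12)),
                 RegionSpec("blobs", comb(12)),
                 RegionSpec("cores", comb(12))),
        shared_peaks=comb(4),
        noise=noise,
        mz_range=(lo, hi),
        n_channels=n_channels,
        seed=seed,
        layout=layout,
    )


@pytest.fixture(scope="session")
def small_phantom():
    """(dataset, truth_labels, spec) for a 16x16, 400-channel phantom."""
    spec = small_spec()
    dataset, truth = generate_phantom(spec)
    return dataset, truth, spec


@pytest.fixture(scope="session")
def liver_phantom():
    """(dataset, truth_labels, spec) for the default 64x64, 4000-channel phantom."""
    spec = default_liver_like_spec(seed=0)
    dataset, truth = generate_phantom(spec)
    return dataset, truth, spec


@pytest.fixture(scope="session")
def liver_imzml(liver_phantom, tmp_path_factory):
    """The default phantom written to disk as an imzML + ibd pair."""
    dataset, truth, spec = liver_phantom
    path = tmp_path_factory.mktemp("liver") / "phantom.imzML"
    write_imzml(dataset, path)
    return path, truth


@pytest.fixture()
def tiny_dataset():
    """4x4-pixel, 100-channel dataset with deterministic random intensities."""
    rng = np.random.default_rng(42)
    coords = [(x, y) for y in range(1, 5) for x in range(1, 5)]
    mz = np.linspace(600.0, 700.0, 100)
    intensities = rng.uniform(0.0, 50.0, (16, 100))
    return InMemoryMSI(coords, mz, intensities)
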