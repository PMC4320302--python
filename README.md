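# rpmsi — random-projection segmentation of mass spectrometry images

`rpmsi` segments mass spectrometry imaging (MSI) data by projecting each
pixel's spectrum onto a seeded Gaussian random basis (A = QX), clustering the
projected scores with k-means, and recovering per-cluster molecular profiles
from the original spectra. Because the basis is data-independent, spectra are
processed one at a time: the full channels-by-pixels matrix is never held in
memory.

Main components:

- **`rpmsi.io`** — minimal imzML 1.1 reader/writer (continuous and processed
  modes) exposing a streaming one-spectrum-at-a-time handle. Processed-mode
  peak lists are resampled onto a common axis by fixed-width binning
  (`bin_width` is required, in Daltons).
- **`rpmsi.projection`** — Gaussian basis generation (`make_basis`), streaming
  projection (`project_dataset`), and prefix-preserving basis extension
  (`extend_basis`); rows are keyed by `(seed, row index)` so extension never
  changes existing rows.
- **`rpmsi.selection`** — automatic choice of the projection count: the
  normalized first singular value of row-subsets of the score matrix is
  fitted with `y = a·exp(−b·x) + c`; the elbow is the analytic point of
  maximum curvature, and the selected count is where curvature falls to
  two-thirds (configurable) of its maximum.
- **`rpmsi.segmentation`** — seeded Lloyd k-means on score columns, map
  rendering, centroid distance matrices, and streaming per-cluster mean
  spectra.
- **`rpmsi.evaluation`** — label-permutation-invariant agreement between
  segmentations (co-assignment correlation + adjusted Rand index), the
  multi-basis stability experiment, a streaming PCA baseline, and
  maximum-window peak picking.
- **`rpmsi.phantom`** — synthetic phantoms with known region structure for
  end-to-end validation (`default_liver_like_spec()` gives a 64×64, 4-region,
  4000-channel phantom over m/z 600–950).

## CLI

```sh
# generate a phantom and write it as imzML + ground truth
rpmsi phantom --out runs/phantom --seed 0

# full pipeline with a fixed projection count
rpmsi run --input runs/phantom/phantom.imzML --out runs/seg \
    --projections 150 --clusters 4 --basis-seed 0 --kmeans-seed 0

# or let the elbow criterion choose the count
rpmsi run --input runs/phantom/phantom.imzML --out runs/auto \
    --projections auto --clusters 4

# individual stages
rpmsi project --input data.imzML --out scores.npz --k 150 --seed 0
rpmsi select  --scores scores.npz --out selection.json
rpmsi segment --scores scores.npz --out segdir --clusters 4
rpmsi profiles --input data.imzML --labels segdir/labels.tsv --out profiles.tsv
rpmsi peaks   --input data.imzML --out peaks.tsv --window 7 --min-intensity 10

# reproducibility experiments
rpmsi evaluate stability --input data.imzML --out stab \
    --counts 5,25,100,200 --repeats 5 --clusters 4
rpmsi evaluate pca-compare --input data.imzML --out pca.json \
    --components 100 --clusters 4
```

`run` writes a manifest (all seeds, parameters, output checksums); identical
seeds reproduce every output byte-for-byte. Exit codes: 0 success, 2
configuration error, 3 I/O error, 4 numerical failure.

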