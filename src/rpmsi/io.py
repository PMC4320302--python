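"""imzML 1.1 reading/writing and streaming access to MSI datasets.

The reader never materializes the full m-by-n intensity matrix: it exposes
metadata (shared m/z axis, pixel coordinates) up front and yields one
spectrum at a time in a deterministic order (ascending y, then x; pixel
coordinates are 1-based per the imzML convention).

Continuous-mode files share a single m/z axis stored once in the ``.ibd``
companion.  Processed-mode files store a peak list per pixel; these are
resampled onto a common axis by summing peak intensities into fixed-width
bins spanning the global m/z range, with the bin width a required
configuration value (there is no safe default).
"""

from __future__ import annotations

import hashlib
import logging
import struct
import uuid
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from rpmsi.errors import ConfigurationError, DataFormatError, DomainError

logger = logging.getLogger(__name__)

Coord = tuple[int, int]

# CV accessions used by the writer and recognised by the reader.
_ACC_CONTINUOUS = "IMS:1000030"
_ACC_PROCESSED = "IMS:1000031"
_ACC_UUID = "IMS:1000080"
_ACC_SHA1 = "IMS:1000091"
_ACC_POS_X = "IMS:1000050"
_ACC_POS_Y = "IMS:1000051"
_ACC_EXT_OFFSET = "IMS:1000102"
_ACC_EXT_LENGTH = "IMS:1000103"
_ACC_EXT_ENCODED = "IMS:1000104"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"

_DTYPE_ACCESSIONS = {
    "MS:1000521": np.dtype("<f4"),  # 32-bit float
    "MS:1000523": np.dtype("<f8"),  # 64-bit float
    "MS:1000519": np.dtype("<i4"),  # 32-bit integer
    "MS:1000522": np.dtype("<i8"),  # 64-bit integer
}


class MSIDataset:
    """Streaming interface over an MSI dataset.

    Subclasses provide ``mz_axis``, ``pixel_coords`` and ``iter_spectra``;
    iteration yields ``((x, y), intensities)`` pairs in ascending (y, x)
    order, one pixel at a time.
    """

    mz_axis: np.ndarray
    pixel_coords: np.ndarray  # (n, 2) int array of (x, y)

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_coords)

    @property
    def n_channels(self) -> int:
        return len(self.mz_axis)

    def iter_spectra(self) -> Iterator[tuple[Coord, np.ndarray]]:
        raise NotImplementedError

    def __iter__(self) -> Iterator[tuple[Coord, np.ndarray]]:
        return self.iter_spectra()

    def __len__(self) -> int:
        return self.n_pixels

    def to_matrix(self) -> np.ndarray:
        """Materialize the full m-by-n matrix (columns = pixels). Test/debug use."""
        out = np.empty((self.n_channels, self.n_pixels), dtype=np.float64)
        for j, (_, x) in enumerate(self.iter_spectra()):
            out[:, j] = x
        return out

    def mean_spectrum(self) -> np.ndarray:
        """Streaming mean over all pixels."""
        acc = np.zeros(self.n_channels, dtype=np.float64)
        for _, x in self.iter_spectra():
            acc += x
        return acc / max(self.n_pixels, 1)


def _validate_axis_and_coords(mz_axis: np.ndarray, coords: np.ndarray) -> None:
    if mz_axis.ndim != 1 or len(mz_axis) == 0:
        raise DomainError("mz_axis must be a non-empty 1-D array")
    if np.any(np.diff(mz_axis) <= 0):
        raise DomainError("mz_axis must be strictly increasing")
    if len(np.unique(coords, axis=0)) != len(coords):
        raise DomainError("pixel coordinates must be unique")


def _sort_order(coords: np.ndarray) -> np.ndarray:
    """Deterministic pixel order: ascending y, then x."""
    return np.lexsort((coords[:, 0], coords[:, 1]))


class InMemoryMSI(MSIDataset):
    """MSI dataset held fully in memory (phantoms, small fixtures).

    Parameters
    ----------
    coords : (n, 2) array of 1-based integer (x, y) grid positions.
    mz_axis : (m,) strictly increasing m/z values in Daltons.
    intensities : (n, m) array, one row per pixel, aligned with ``coords``.
    """

    def __init__(self, coords: Sequence[Coord] | np.ndarray, mz_axis: np.ndarray,
                 intensities: np.ndarray):
        coords = np.asarray(coords, dtype=np.int64).reshape(-1, 2)
        mz_axis = np.asarray(mz_axis, dtype=np.float64)
        intensities = np.asarray(intensities, dtype=np.float64)
        if intensities.shape != (len(coords), len(mz_axis)):
            raise DomainError(
                f"intensities shape {intensities.shape} inconsistent with "
                f"{len(coords)} pixels x {len(mz_axis)} channels"
            )
        _validate_axis_and_coords(mz_axis, coords)
        if np.any(intensities < 0):
            logger.warning("clamping %d negative intensity values to 0",
                           int(np.sum(intensities < 0)))
            intensities = np.clip(intensities, 0.0, None)
        order = _sort_order(coords)
        self.pixel_coords = coords[order]
        self.mz_axis = mz_axis
        self._intensities = intensities[order]

    def iter_spectra(self) -> Iterator[tuple[Coord, np.ndarray]]:
        for c, row in zip(self.pixel_coords, self._intensities):
            yield (int(c[0]), int(c[1])), row


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _ibd_paths(path: str | Path) -> tuple[Path, Path]:
    imzml = Path(path)
    return imzml, imzml.with_suffix(".ibd")


def _cv(parent: ET.Element, cv_ref: str, accession: str, name: str,
        value: str | None = None) -> None:
    attrs = {"cvRef": cv_ref, "accession": accession, "name": name}
    if value is not None:
        attrs["value"] = value
    ET.SubElement(parent, "cvParam", attrs)


def _array_group(parent: ET.Element, group_id: str, array_accession: str,
                 array_name: str) -> None:
    g = ET.SubElement(parent, "referenceableParamGroup", {"id": group_id})
    _cv(g, "MS", array_accession, array_name)
    _cv(g, "MS", "MS:1000523", "64-bit float")
    _cv(g, "MS", "MS:1000576", "no compression")
    _cv(g, "IMS", "IMS:1000101", "external data", "true")


def _binary_array(parent: ET.Element, group_ref: str, length: int,
                  offset: int) -> None:
    b = ET.SubElement(parent, "binaryDataArray", {"encodedLength": "0"})
    ET.SubElement(b, "referenceableParamGroupRef", {"ref": group_ref})
    _cv(b, "IMS", _ACC_EXT_LENGTH, "external array length", str(length))
    _cv(b, "IMS", _ACC_EXT_ENCODED, "external encoded length", str(length * 8))
    _cv(b, "IMS", _ACC_EXT_OFFSET, "external offset", str(offset))
    ET.SubElement(b, "binary")


def write_imzml(dataset: MSIDataset, path: str | Path) -> tuple[Path, Path]:
    """Write a dataset as a continuous-mode imzML + ibd pair.

    The shared m/z axis is stored once; intensities are stored as little-
    endian 64-bit floats so a write/read round trip is bit-identical.  The
    ibd UUID is derived from the payload so identical datasets produce
    byte-identical files.

    Returns the (imzml_path, ibd_path) pair.
    """
    if dataset.n_pixels == 0:
        raise DomainError("refusing to write an empty dataset (0 pixels)")
    imzml_path, ibd_path = _ibd_paths(path)

    m = dataset.n_channels
    mz_bytes = np.ascontiguousarray(dataset.mz_axis, dtype="<f8").tobytes()

    # Deterministic UUID from the payload (hash of axis + spectra).
    h = hashlib.sha1()
    h.update(mz_bytes)
    spectra: list[tuple[Coord, bytes]] = []
    for coord, x in dataset.iter_spectra():
        if len(x) != m:
            raise DomainError(f"spectrum at {coord} has {len(x)} channels, expected {m}")
        payload = np.ascontiguousarray(x, dtype="<f8").tobytes()
        h.update(struct.pack("<qq", coord[0], coord[1]))
        h.update(payload)
        spectra.append((coord, payload))
    file_uuid = uuid.UUID(bytes=h.digest()[:16])

    with open(ibd_path, "wb") as ibd:
        ibd.write(file_uuid.bytes)
        mz_offset = ibd.tell()
        ibd.write(mz_bytes)
        intensity_offsets = []
        for _, payload in spectra:
            intensity_offsets.append(ibd.tell())
            ibd.write(payload)
    ibd_sha1 = hashlib.sha1(ibd_path.read_bytes()).hexdigest()

    root = ET.Element("mzML", {"xmlns": "http://psi.hupo.org/ms/mzml", "version": "1.1"})
    cv_list = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(cv_list, "cv", {"id": "MS", "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology", "URI": "http://psidev.info/ms/mzML/psi-ms.obo"})
    ET.SubElement(cv_list, "cv", {"id": "IMS", "fullName": "Imaging MS Ontology", "URI": "http://www.maldi-msi.org/download/imzml/imagingMS.obo"})
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, "IMS", _ACC_CONTINUOUS, "continuous")
    _cv(fcontent, "IMS", _ACC_UUID, "universally unique identifier",
        "{" + str(file_uuid) + "}")
    _cv(fcontent, "IMS", _ACC_SHA1, "ibd SHA-1", ibd_sha1)

    groups = ET.SubElement(root, "referenceableParamGroupList", {"count": "2"})
    _array_group(groups, "mzArray", _ACC_MZ_ARRAY, "m/z array")
    _array_group(groups, "intensityArray", _ACC_INT_ARRAY, "intensity array")

    coords_arr = dataset.pixel_coords
    settings = ET.SubElement(root, "scanSettingsList", {"count": "1"})
    ss = ET.SubElement(settings, "scanSettings", {"id": "scanSettings1"})
    _cv(ss, "IMS", "IMS:1000042", "max count of pixels x", str(int(coords_arr[:, 0].max())))
    _cv(ss, "IMS", "IMS:1000043", "max count of pixels y", str(int(coords_arr[:, 1].max())))

    run = ET.SubElement(root, "run", {"id": "run1"})
    slist = ET.SubElement(run, "spectrumList", {"count": str(dataset.n_pixels)})
    for idx, (coord, offset) in enumerate(zip([tuple(map(int, c)) for c in coords_arr],
                                              intensity_offsets)):
        spec = ET.SubElement(slist, "spectrum",
                             {"id": f"spectrum={idx + 1}", "index": str(idx),
                              "defaultArrayLength": str(m)})
        scan_list = ET.SubElement(spec, "scanList", {"count": "1"})
        scan = ET.SubElement(scan_list, "scan")
        _cv(scan, "IMS", _ACC_POS_X, "position x", str(coord[0]))
        _cv(scan, "IMS", _ACC_POS_Y, "position y", str(coord[1]))
        arrays = ET.SubElement(spec, "binaryDataArrayList", {"count": "2"})
        _binary_array(arrays, "mzArray", m, mz_offset)
        _binary_array(arrays, "intensityArray", m, offset)

    ET.indent(root)
    ET.ElementTree(root).write(imzml_path, xml_declaration=True, encoding="utf-8")
    return imzml_path, ibd_path


def write_processed_imzml(coords: Sequence[Coord], mz_lists: Sequence[np.ndarray],
                          intensity_lists: Sequence[np.ndarray],
                          path: str | Path) -> tuple[Path, Path]:
    """Write a processed-mode imzML + ibd pair (per-pixel peak lists).

    Used to exercise the processed-mode reading/binning path; real data in
    this mode comes from vendor converters.
    """
    if len(coords) == 0:
        raise DomainError("refusing to write an empty dataset (0 pixels)")
    if not (len(coords) == len(mz_lists) == len(intensity_lists)):
        raise DomainError("coords, mz_lists and intensity_lists must have equal length")
    imzml_path, ibd_path = _ibd_paths(path)

    h = hashlib.sha1()
    payloads = []
    for (x, y), mzs, ints in zip(coords, mz_lists, intensity_lists):
        mzs = np.ascontiguousarray(mzs, dtype="<f8")
        ints = np.ascontiguousarray(ints, dtype="<f8")
        if len(mzs) != len(ints):
            raise DomainError("per-pixel m/z and intensity lists must align")
        h.update(struct.pack("<qq", x, y))
        h.update(mzs.tobytes())
        h.update(ints.tobytes())
        payloads.append((mzs.tobytes(), ints.tobytes(), len(mzs)))
    file_uuid = uuid.UUID(bytes=h.digest()[:16])

    offsets = []
    with open(ibd_path, "wb") as ibd:
        ibd.write(file_uuid.bytes)
        for mz_b, int_b, _ in payloads:
            mz_off = ibd.tell()
            ibd.write(mz_b)
            int_off = ibd.tell()
            ibd.write(int_b)
            offsets.append((mz_off, int_off))

    root = ET.Element("mzML", {"xmlns": "http://psi.hupo.org/ms/mzml", "version": "1.1"})
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, "IMS", _ACC_PROCESSED, "processed")
    _cv(fcontent, "IMS", _ACC_UUID, "universally unique identifier",
        "{" + str(file_uuid) + "}")
    groups = ET.SubElement(root, "referenceableParamGroupList", {"count": "2"})
    _array_group(groups, "mzArray", _ACC_MZ_ARRAY, "m/z array")
    _array_group(groups, "intensityArray", _ACC_INT_ARRAY, "intensity array")
    run = ET.SubElement(root, "run", {"id": "run1"})
    slist = ET.SubElement(run, "spectrumList", {"count": str(len(coords))})
    for idx, ((x, y), (_, _, n_peaks), (mz_off, int_off)) in enumerate(
            zip(coords, payloads, offsets)):
        spec = ET.SubElement(slist, "spectrum",
                             {"id": f"spectrum={idx + 1}", "index": str(idx),
                              "defaultArrayLength": str(n_peaks)})
        scan_list = ET.SubElement(spec, "scanList", {"count": "1"})
        scan = ET.SubElement(scan_list, "scan")
        _cv(scan, "IMS", _ACC_POS_X, "position x", str(int(x)))
        _cv(scan, "IMS", _ACC_POS_Y, "position y", str(int(y)))
        arrays = ET.SubElement(spec, "binaryDataArrayList", {"count": "2"})
        _binary_array(arrays, "mzArray", n_peaks, mz_off)
        _binary_array(arrays, "intensityArray", n_peaks, int_off)
    ET.indent(root)
    ET.ElementTree(root).write(imzml_path, xml_declaration=True, encoding="utf-8")
    return imzml_path, ibd_path


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _collect_cv_params(elem: ET.Element) -> dict[str, str]:
    out = {}
    for child in elem:
        if _local(child.tag) == "cvParam":
            out[child.get("accession", "")] = child.get("value", "")
    return out


@dataclass
class _ArrayRef:
    offset: int
    length: int
    dtype: np.dtype


@dataclass
class _SpectrumRecord:
    coord: Coord
    mz: _ArrayRef
    intensity: _ArrayRef


def _read_array(ibd, ref: _ArrayRef) -> np.ndarray:
    ibd.seek(ref.offset)
    raw = ibd.read(ref.length * ref.dtype.itemsize)
    if len(raw) != ref.length * ref.dtype.itemsize:
        raise DataFormatError("ibd file truncated while reading array "
                              f"at offset {ref.offset}")
    return np.frombuffer(raw, dtype=ref.dtype).astype(np.float64)


class ImzMLReader(MSIDataset):
    """Streaming reader over an imzML + ibd pair.

    Iteration yields one ``((x, y), intensities)`` pair per pixel in
    ascending (y, x) order.  For processed-mode files a ``bin_width`` (in
    Daltons) must be supplied; peak intensities are summed into fixed-width
    bins spanning the global m/z range and the axis holds bin centers.
    """

    def __init__(self, path: str | Path, bin_width: float | None = None):
        imzml_path, ibd_path = _ibd_paths(path)
        if not imzml_path.exists():
            raise DataFormatError(f"imzML file not found: {imzml_path}")
        if not ibd_path.exists():
            raise DataFormatError(f"ibd companion not found: {ibd_path}")
        self._ibd_path = ibd_path
        self.bin_width = bin_width

        try:
            tree = ET.parse(imzml_path)
        except ET.ParseError as exc:
            raise DataFormatError(f"cannot parse imzML XML in {imzml_path}: {exc}") from exc
        root = tree.getroot()

        self.continuous = self._detect_mode(root)
        if not self.continuous and bin_width is None:
            raise ConfigurationError(
                "processed-mode imzML requires a bin_width (Daltons); none configured"
            )
        if bin_width is not None and bin_width <= 0:
            raise ConfigurationError("bin_width must be positive")

        group_roles, group_dtypes = self._parse_param_groups(root)
        records = self._parse_spectra(root, group_roles, group_dtypes, imzml_path)
        if not records:
            raise DataFormatError(f"no spectra found in {imzml_path}")
        records.sort(key=lambda r: (r.coord[1], r.coord[0]))
        coords = np.array([r.coord for r in records], dtype=np.int64)
        if len(np.unique(coords, axis=0)) != len(coords):
            raise DataFormatError(f"duplicate pixel coordinates in {imzml_path}")
        self.pixel_coords = coords
        self._records = records

        ibd_size = ibd_path.stat().st_size
        max_end = max(max(r.mz.offset + r.mz.length * r.mz.dtype.itemsize,
                          r.intensity.offset + r.intensity.length * r.intensity.dtype.itemsize)
                      for r in records)
        if ibd_size < max_end:
            raise DataFormatError(
                f"ibd file {ibd_path} truncated: {ibd_size} bytes, spectra "
                f"reference up to byte {max_end}"
            )

        with open(ibd_path, "rb") as ibd:
            if self.continuous:
                self.mz_axis = _read_array(ibd, records[0].mz)
                if np.any(np.diff(self.mz_axis) <= 0):
                    raise DataFormatError(f"m/z axis in {imzml_path} is not strictly increasing")
            else:
                self._bin_lo, bin_hi = self._scan_mz_range(ibd)
                n_bins = int(np.floor((bin_hi - self._bin_lo) / bin_width)) + 1
                self.mz_axis = self._bin_lo + (np.arange(n_bins) + 0.5) * bin_width
        self._warned_negative = False

    @staticmethod
    def _detect_mode(root: ET.Element) -> bool:
        for elem in root.iter():
            if _local(elem.tag) == "fileContent":
                params = _collect_cv_params(elem)
                if _ACC_CONTINUOUS in params:
                    return True
                if _ACC_PROCESSED in params:
                    return False
        raise DataFormatError("imzML fileContent declares neither continuous nor processed mode")

    @staticmethod
    def _parse_param_groups(root: ET.Element) -> tuple[dict[str, str], dict[str, np.dtype]]:
        roles: dict[str, str] = {}
        dtypes: dict[str, np.dtype] = {}
        for elem in root.iter():
            if _local(elem.tag) != "referenceableParamGroup":
                continue
            gid = elem.get("id", "")
            params = _collect_cv_params(elem)
            if _ACC_MZ_ARRAY in params:
                roles[gid] = "mz"
            elif _ACC_INT_ARRAY in params:
                roles[gid] = "intensity"
            for acc, dt in _DTYPE_ACCESSIONS.items():
                if acc in params:
                    dtypes[gid] = dt
        return roles, dtypes

    def _parse_spectra(self, root, group_roles, group_dtypes, imzml_path):
        records = []
        for spec in root.iter():
            if _local(spec.tag) != "spectrum":
                continue
            x = y = None
            arrays: dict[str, _ArrayRef] = {}
            for elem in spec.iter():
                tag = _local(elem.tag)
                if tag == "scan":
                    params = _collect_cv_params(elem)
                    if _ACC_POS_X in params:
                        x = int(params[_ACC_POS_X])
                    if _ACC_POS_Y in params:
                        y = int(params[_ACC_POS_Y])
                elif tag == "binaryDataArray":
                    role = None
                    dtype = np.dtype("<f8")
                    params = _collect_cv_params(elem)
                    for child in elem:
                        if _local(child.tag) == "referenceableParamGroupRef":
                            ref = child.get("ref", "")
                            role = group_roles.get(ref)
                            dtype = group_dtypes.get(ref, dtype)
                    if _ACC_MZ_ARRAY in params:
                        role = "mz"
                    elif _ACC_INT_ARRAY in params:
                        role = "intensity"
                    for acc, dt in _DTYPE_ACCESSIONS.items():
                        if acc in params:
                            dtype = dt
                    if role and _ACC_EXT_OFFSET in params and _ACC_EXT_LENGTH in params:
                        arrays[role] = _ArrayRef(offset=int(params[_ACC_EXT_OFFSET]),
                                                 length=int(params[_ACC_EXT_LENGTH]),
                                                 dtype=dtype)
            if x is None or y is None:
                raise DataFormatError(f"spectrum without pixel position in {imzml_path}")
            if "mz" not in arrays or "intensity" not in arrays:
                raise DataFormatError(f"spectrum at ({x}, {y}) lacks m/z or intensity array")
            records.append(_SpectrumRecord(coord=(x, y), mz=arrays["mz"],
                                           intensity=arrays["intensity"]))
        return records

    def _scan_mz_range(self, ibd) -> tuple[float, float]:
        lo, hi = np.inf, -np.inf
        for r in self._records:
            mzs = _read_array(ibd, r.mz)
            if len(mzs):
                lo = min(lo, float(mzs.min()))
                hi = max(hi, float(mzs.max()))
        if not np.isfinite(lo):
            raise DataFormatError("processed-mode file contains no peaks")
        return lo, hi

    def _clamp(self, x: np.ndarray) -> np.ndarray:
        neg = x < 0
        if np.any(neg):
            if not self._warned_negative:
                logger.warning("clamping negative intensities to 0 in %s", self._ibd_path)
                self._warned_negative = True
            x = np.where(neg, 0.0, x)
        return x

    def iter_spectra(self) -> Iterator[tuple[Coord, np.ndarray]]:
        with open(self._ibd_path, "rb") as ibd:
            for r in self._records:
                intensities = _read_array(ibd, r.intensity)
                if self.continuous:
                    if len(intensities) != self.n_channels:
                        raise DataFormatError(
                            f"spectrum at {r.coord} has {len(intensities)} values, "
                            f"expected {self.n_channels}")
                    yield r.coord, self._clamp(intensities)
                else:
                    mzs = _read_array(ibd, r.mz)
                    binned = np.zeros(self.n_channels, dtype=np.float64)
                    idx = np.floor((mzs - self._bin_lo) / self.bin_width).astype(np.int64)
                    idx = np.clip(idx, 0, self.n_channels - 1)
                    np.add.at(binned, idx, intensities)
                    yield r.coord, self._clamp(binned)


def read_imzml(path: str | Path, bin_width: float | None = None) -> ImzMLReader:
    """Open an imzML + ibd pair as a streaming :class:`MSIDataset` handle."""
    return ImzMLReader(path, bin_width=bin_width)
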