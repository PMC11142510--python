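"""Hyperspectral cube and label-map containers with ENVI/GeoTIFF/HDF5 I/O.

A scene is an ``M x N x Q`` reflectance raster (band-last, 0-based
``(row, col)`` indexing) plus an integer label raster of the same spatial
shape, where 0 marks unlabeled background and 1..K the tree-species
classes.  On-disk support covers the three formats hyperspectral data
commonly travels in:

* ENVI raster — a plain-text ``.hdr`` next to a flat binary file in BSQ,
  BIL or BIP interleave; wavelengths are read from and written to the
  header.
* GeoTIFF — via :mod:`tifffile`; the affine geotransform is carried in the
  standard GeoTIFF pixel-scale / tiepoint tags.
* HDF5 — datasets ``cube``, ``labels``, ``wavelengths`` in one archive.

Whatever the on-disk interleave, the in-memory layout is always band-last.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

__all__ = ["HSICube", "LabelMap", "load_cube", "save_cube",
           "load_labels", "save_labels"]

# ENVI "data type" codes for the dtypes we read/write
_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16, 13: np.uint32}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HSICube:
    """An M x N x Q reflectance raster (rows x cols x bands, band-last)."""

    data: np.ndarray
    wavelengths: np.ndarray | None = None
    geotransform: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be 3-D (M, N, Q); got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=float)
            if self.wavelengths.shape != (self.data.shape[2],):
                raise ValueError("wavelength list length must equal band count")
            if np.any(np.diff(self.wavelengths) <= 0):
                raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class LabelMap:
    """Integer class raster: 0 = unlabeled background, 1..K = species."""

    labels: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0")
        k = int(self.labels.max())
        if not self.class_names:
            self.class_names = [f"class_{i}" for i in range(1, k + 1)]
        elif len(self.class_names) < k:
            raise ValueError(f"{k} classes present but only "
                             f"{len(self.class_names)} names given")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


# ---------------------------------------------------------------------------
# ENVI
# ---------------------------------------------------------------------------

def _parse_envi_header(hdr_path: Path) -> dict:
    text = hdr_path.read_text()
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if in_braces:
            buf.append(line.rstrip("}").strip())
            if line.endswith("}"):
                fields[key] = " ".join(buf).strip()
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip().lower(), val.strip()
        if val.startswith("{") and not val.endswith("}"):
            buf, in_braces = [val.lstrip("{").strip()], True
        else:
            fields[key] = val.strip("{} ").strip()
    return fields


def _read_envi(path: Path) -> HSICube:
    path = Path(path)
    hdr = path.with_suffix(".hdr") if path.suffix != ".hdr" else path
    if not hdr.exists():
        raise IOError(f"ENVI header not found: {hdr}")
    fields = _parse_envi_header(hdr)
    data_file = hdr.with_suffix(".img")
    if not data_file.exists():
        candidates = [hdr.with_suffix(ext) for ext in (".dat", ".bin", "")]
        data_file = next((c for c in candidates if c.exists() and c != hdr), None)
        if data_file is None:
            raise IOError(f"ENVI data file not found next to {hdr}")
    lines = int(fields["lines"])
    samples = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = np.dtype(_ENVI_DTYPES[int(fields["data type"])])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bsq").lower()
    raw = np.fromfile(data_file, dtype=dtype)
    expected = lines * samples * bands
    if raw.size != expected:
        raise IOError(f"ENVI data size mismatch in {data_file}: "
                      f"expected {expected} values, found {raw.size}")
    if interleave == "bsq":          # (bands, lines, samples)
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":        # (lines, bands, samples)
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":        # (lines, samples, bands)
        cube = raw.reshape(lines, samples, bands)
    else:
        raise IOError(f"unsupported ENVI interleave '{interleave}'")
    wl = None
    if "wavelength" in fields:
        wl = np.array([float(w) for w in fields["wavelength"].split(",") if w.strip()])
    return HSICube(np.ascontiguousarray(cube), wavelengths=wl)


def _write_envi(cube: HSICube, path: Path, interleave: str = "bsq") -> None:
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unknown interleave '{interleave}'")
    data = np.asarray(cube.data)
    if data.dtype not in _ENVI_CODES:
        data = data.astype(np.float32)
    m, n, q = data.shape
    if interleave == "bsq":
        on_disk = data.transpose(2, 0, 1)
    elif interleave == "bil":
        on_disk = data.transpose(0, 2, 1)
    else:
        on_disk = data
    img = path.with_suffix(".img")
    np.ascontiguousarray(on_disk).tofile(img)
    lines = ["ENVI",
             f"samples = {n}", f"lines = {m}", f"bands = {q}",
             "header offset = 0", "file type = ENVI Standard",
             f"data type = {_ENVI_CODES[data.dtype]}",
             f"interleave = {interleave}", "byte order = 0"]
    if cube.wavelengths is not None:
        wl = ", ".join(f"{w:g}" for w in cube.wavelengths)
        lines.append(f"wavelength = {{ {wl} }}")
    path.with_suffix(".hdr").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GeoTIFF
# ---------------------------------------------------------------------------

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


def _read_geotiff(path: Path) -> HSICube:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        page = tif.pages[0]
        scale = page.tags.get(_TAG_PIXEL_SCALE)
        tie = page.tags.get(_TAG_TIEPOINT)
        scale = None if scale is None else tuple(scale.value)
        tie = None if tie is None else tuple(tie.value)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    elif arr.ndim == 3 and arr.shape[0] < min(arr.shape[1], arr.shape[2]):
        # planar (bands, rows, cols) layout
        arr = arr.transpose(1, 2, 0)
    geo = None
    if scale is not None and tie is not None:
        sx, sy = float(scale[0]), float(scale[1])
        i, j, _, x, y, _ = (float(v) for v in tie[:6])
        geo = (x - j * sx, sx, 0.0, y + i * sy, 0.0, -sy)
    return HSICube(np.ascontiguousarray(arr), geotransform=geo)


def _write_geotiff(cube: HSICube, path: Path) -> None:
    import tifffile

    extratags = []
    if cube.geotransform is not None:
        x0, sx, _, y0, _, sy = cube.geotransform
        extratags = [
            (_TAG_PIXEL_SCALE, "d", 3, (sx, abs(sy), 0.0)),
            (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        ]
    data = np.asarray(cube.data, dtype=np.float32)
    tifffile.imwrite(str(path), data, photometric="minisblack",
                     planarconfig="contig", extratags=extratags)


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------

def _read_hdf5(path: Path) -> tuple[HSICube, LabelMap | None]:
    with h5py.File(path, "r") as f:
        if "cube" not in f:
            raise IOError(f"HDF5 file {path} has no 'cube' dataset")
        data = f["cube"][()]
        wl = f["wavelengths"][()] if "wavelengths" in f else None
        geo = tuple(f.attrs["geotransform"]) if "geotransform" in f.attrs else None
        labels = None
        if "labels" in f:
            names = json.loads(f.attrs.get("class_names", "[]"))
            labels = LabelMap(f["labels"][()].astype(np.int64), class_names=names)
    return HSICube(data, wavelengths=wl, geotransform=geo), labels


def save_cube(cube: HSICube, path, *, format: str | None = None,
              interleave: str = "bsq", labels: LabelMap | None = None) -> None:
    """Write a cube (and optionally its labels, HDF5 only) to disk."""
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "envi":
        _write_envi(cube, path, interleave=interleave)
    elif fmt == "geotiff":
        _write_geotiff(cube, path)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("cube", data=cube.data, track_times=False)
            if cube.wavelengths is not None:
                f.create_dataset("wavelengths", data=cube.wavelengths, track_times=False)
            if cube.geotransform is not None:
                f.attrs["geotransform"] = cube.geotransform
            if labels is not None:
                f.create_dataset("labels", data=labels.labels, track_times=False)
                f.attrs["class_names"] = json.dumps(labels.class_names)
    else:
        raise ValueError(f"unknown format '{fmt}'")


def load_cube(path, *, format: str | None = None) -> HSICube:
    """Read a cube from ENVI, GeoTIFF or HDF5 into band-last layout."""
    path = Path(path)
    if not path.exists() and not path.with_suffix(".hdr").exists():
        raise IOError(f"no such file: {path}")
    fmt = format or _guess_format(path)
    if fmt == "envi":
        return _read_envi(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    if fmt == "hdf5":
        cube, _ = _read_hdf5(path)
        return cube
    raise ValueError(f"unknown format '{fmt}'")


def load_labels(path) -> LabelMap:
    """Read a label map from an HDF5 scene archive."""
    _, labels = _read_hdf5(Path(path))
    if labels is None:
        raise IOError(f"{path} carries no 'labels' dataset")
    return labels


def save_labels(labels: LabelMap, path) -> None:
    with h5py.File(path, "a") as f:
        if "labels" in f:
            del f["labels"]
        f.create_dataset("labels", data=labels.labels, track_times=False)
        f.attrs["class_names"] = json.dumps(labels.class_names)


def _guess_format(path: Path) -> str:
    ext = path.suffix.lower()
    if ext in (".h5", ".hdf5", ".he5"):
        return "hdf5"
    if ext in (".tif", ".tiff"):
        return "geotiff"
    if ext in (".img", ".hdr", ".dat", ".raw", ".bsq", ".bil", ".bip", ""):
        return "envi"
    raise ValueError(f"cannot infer raster format from extension '{ext}'")
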