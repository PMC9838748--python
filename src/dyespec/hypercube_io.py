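"""Hyperspectral cube container, camera spectral grid, and ENVI-style file I/O.

A hyperspectral cube is a 3-D raster ``I(m, n, k)`` — two spatial axes (row,
column) and one spectral axis of narrow contiguous bands.  Cubes are stored on
disk as an ENVI text header (``.hdr``) next to a raw band-sequential (BSQ)
binary file, the de-facto interchange format for line-scan hyperspectral
cameras.  All coordinates are 0-based; rectangular regions are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "WavelengthGrid",
    "SpectralCube",
    "CameraSpec",
    "EnviFormatError",
    "MaskError",
    "default_grid",
    "default_camera",
    "write_envi",
    "read_envi",
    "load_mask",
]

#: Span and channel count of the reference line-scan camera.
_RANGE_NM = (400.0, 1000.0)
_N_CHANNELS = 128

# ENVI numeric data-type codes <-> numpy dtypes (little-endian).
_ENVI_DTYPES = {
    1: np.dtype("<u1"),
    2: np.dtype("<i2"),
    4: np.dtype("<f4"),
    5: np.dtype("<f8"),
    12: np.dtype("<u2"),
}
_DTYPE_CODES = {v: k for k, v in _ENVI_DTYPES.items()}


class EnviFormatError(ValueError):
    """Malformed, contradictory or unsupported ENVI header / data file."""


class MaskError(ValueError):
    """Region mask does not match the target raster or selects nothing."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band centers (nm) of a spectral axis."""

    band_centers: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.band_centers, dtype=float)
        if centers.ndim != 1 or centers.size < 1:
            raise ValueError("band_centers must be a non-empty 1-D array")
        if not np.all(np.isfinite(centers)):
            raise ValueError("band_centers must be finite")
        if np.any(np.diff(centers) <= 0):
            raise ValueError("band_centers must be strictly increasing")
        object.__setattr__(self, "band_centers", centers)

    @property
    def count(self) -> int:
        return int(self.band_centers.size)

    @property
    def span_nm(self) -> float:
        return float(self.band_centers[-1] - self.band_centers[0])


@dataclass(frozen=True)
class CameraSpec:
    """Technical characteristics of the acquisition camera (metadata only)."""

    spatial_resolution: int = 696
    spectral_resolution_nm: float = 4.69
    dynamic_range_bits: int = 12
    channels: int = _N_CHANNELS
    dx: float = 1.0
    dy: float = 1.0

    @property
    def dn_max(self) -> int:
        return 2**self.dynamic_range_bits - 1


#: Upper DN bound of the 12-bit sensor.
DN_MAX = CameraSpec().dn_max


@dataclass
class SpectralCube:
    """3-D raster with wavelength metadata.

    ``kind`` flags whether ``values`` are raw sensor counts (``"dn"``, bounded
    by the 12-bit range) or calibrated reflectance (``"reflectance"``,
    non-negative fractions).
    """

    values: np.ndarray
    grid: WavelengthGrid
    kind: str = "dn"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError("cube values must be 3-D (rows, cols, bands)")
        if v.shape[2] != self.grid.count:
            raise ValueError(
                f"cube has {v.shape[2]} planes but grid has {self.grid.count} bands"
            )
        if self.kind not in ("dn", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")
        if not np.all(np.isfinite(v)):
            raise ValueError("cube values must be finite")
        if self.kind == "dn":
            if v.min() < 0 or v.max() > DN_MAX:
                raise ValueError(f"raw DN values must lie in [0, {DN_MAX}]")
        elif v.min() < 0:
            raise ValueError("reflectance values must be non-negative")
        self.values = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def default_grid() -> WavelengthGrid:
    """128 band centers at ``400 + k * (600 / 128)`` nm, k = 0..127.

    The implied 4.6875 nm spacing rounds to the camera's quoted 4.69 nm
    spectral resolution.  Cameras publish their true band centers in the file
    header; an explicit center list read from a header always overrides this
    default.
    """
    lo, hi = _RANGE_NM
    step = (hi - lo) / _N_CHANNELS
    return WavelengthGrid(lo + step * np.arange(_N_CHANNELS))


def default_camera() -> CameraSpec:
    return CameraSpec()


def _paths(path: str | Path) -> tuple[Path, Path]:
    """Resolve a user path to (header, data) file paths."""
    p = Path(path)
    if p.suffix == ".hdr":
        return p, p.with_suffix(".raw")
    if p.suffix == ".raw":
        return p.with_suffix(".hdr"), p
    return p.with_suffix(".hdr"), p.with_suffix(".raw")


def write_envi(cube: SpectralCube, path: str | Path) -> tuple[Path, Path]:
    """Write *cube* as an ENVI header + BSQ binary pair.

    ``path`` may be a bare stem or end in ``.hdr``/``.raw``.  The on-disk
    dtype follows the array dtype (uint8/16, int16, float32/64), so a
    read-back reproduces the raster bit-exactly.  Returns the (header, data)
    paths written.
    """
    hdr_path, raw_path = _paths(path)
    dtype = np.dtype(cube.values.dtype).newbyteorder("<")
    if dtype not in _DTYPE_CODES:
        raise EnviFormatError(f"unsupported cube dtype {cube.values.dtype}")
    rows, cols, bands = cube.shape
    wl = ", ".join(repr(float(w)) for w in cube.grid.band_centers)
    header = (
        "ENVI\n"
        "description = {dyespec spectral cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"cube kind = {cube.kind}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path.write_text(header)
    # BSQ: band-sequential planes, row-major within each plane.
    np.ascontiguousarray(np.moveaxis(cube.values, 2, 0)).astype(dtype).tofile(raw_path)
    return hdr_path, raw_path


def _parse_header(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise EnviFormatError("missing ENVI magic line")
    fields: dict[str, str] = {}
    # Join brace-enclosed multi-line values before splitting on '='.
    body = text.split("\n", 1)[1] if "\n" in text else ""
    buf = ""
    for raw_line in body.splitlines():
        buf = f"{buf} {raw_line}".strip() if buf else raw_line.strip()
        if buf.count("{") > buf.count("}"):
            continue
        if "=" in buf:
            key, val = buf.split("=", 1)
            fields[key.strip().lower()] = val.strip()
        buf = ""
    return fields


def read_envi(path: str | Path) -> SpectralCube:
    """Read an ENVI header + BSQ binary pair written by :func:`write_envi`.

    Raises :class:`EnviFormatError` on missing or contradictory header
    fields, truncated data files, or unsupported interleave schemes.
    """
    hdr_path, raw_path = _paths(path)
    if not hdr_path.exists():
        raise EnviFormatError(f"header file not found: {hdr_path}")
    if not raw_path.exists():
        raise EnviFormatError(f"data file not found: {raw_path}")
    fields = _parse_header(hdr_path.read_text())

    for key in ("samples", "lines", "bands", "data type"):
        if key not in fields:
            raise EnviFormatError(f"header missing required field {key!r}")
    cols, rows, bands = (int(fields[k]) for k in ("samples", "lines", "bands"))
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise EnviFormatError(f"unsupported interleave {interleave!r} (BSQ only)")
    if int(fields.get("byte order", "0")) != 0:
        raise EnviFormatError("only little-endian (byte order = 0) is supported")
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise EnviFormatError(f"unsupported ENVI data type {code}")
    dtype = _ENVI_DTYPES[code]

    offset = int(fields.get("header offset", "0"))
    expected = rows * cols * bands * dtype.itemsize
    raw = raw_path.read_bytes()[offset:]
    if len(raw) != expected:
        raise EnviFormatError(
            f"data file holds {len(raw)} bytes, header implies {expected} "
            f"({rows}x{cols}x{bands} {dtype})"
        )
    planes = np.frombuffer(raw, dtype=dtype).reshape(bands, rows, cols)

    wl_field = fields.get("wavelength")
    if wl_field is None:
        raise EnviFormatError("header missing wavelength list")
    centers = np.array(
        [float(tok) for tok in wl_field.strip("{} \t").split(",") if tok.strip()]
    )
    if centers.size != bands:
        raise EnviFormatError(
            f"{centers.size} wavelengths listed for {bands} declared bands"
        )
    grid = WavelengthGrid(centers)  # rejects non-increasing lists
    kind = fields.get("cube kind", "dn")
    return SpectralCube(np.moveaxis(planes, 0, 2).copy(), grid, kind=kind)


def load_mask(path: str | Path, shape: tuple[int, int]) -> np.ndarray:
    """Load a region-of-interest raster as a boolean mask.

    Nonzero pixels are in-region.  The raster's spatial shape must equal
    *shape*; an all-zero mask is rejected (nothing to analyze).
    """
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # collapse color/alpha: any nonzero channel selects
        img = img.reshape(img.shape[0], img.shape[1], -1).any(axis=2)
    if img.shape != tuple(shape):
        raise MaskError(f"mask shape {img.shape} does not match raster shape {tuple(shape)}")
    mask = img != 0
    if not mask.any():
        raise MaskError("mask selects no pixels")
    return mask
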