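"""ENVI-format I/O for hyperspectral image cubes.

A hyperspectral camera produces a 3-D datacube: a spatial image with a full
reflectance (or raw digital-number) spectrum at every pixel.  The de-facto
container for such cubes is the ENVI pair — a small text header (``.hdr``)
describing dimensions, data type, band interleave and the wavelength list,
next to a raw binary raster.  This module reads and writes that pair for the
three standard interleaves (BIL, BIP, BSQ) and normalises everything to a
single in-memory layout: ``(rows, cols, bands)`` with the band axis last.

Only uncompressed, untiled ENVI rasters are supported.  Unknown header keys
are preserved verbatim and written back on rewrite, so vendor metadata
survives a round-trip even though it is never interpreted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["HyperCube", "read_envi", "write_envi", "EnviFormatError"]

#: ENVI numeric codes for the data types this package handles.
_ENVI_DTYPES = {
    1: np.dtype("uint8"),
    2: np.dtype("int16"),
    3: np.dtype("int32"),
    4: np.dtype("float32"),
    5: np.dtype("float64"),
    12: np.dtype("uint16"),
    13: np.dtype("uint32"),
    14: np.dtype("int64"),
}
_DTYPE_CODES = {v: k for k, v in _ENVI_DTYPES.items()}

_INTERLEAVES = ("bil", "bip", "bsq")


class EnviFormatError(ValueError):
    """Raised when an ENVI header/data pair is malformed or inconsistent."""


@dataclass
class HyperCube:
    """A hyperspectral datacube with its wavelength axis.

    Parameters
    ----------
    data:
        Array of shape ``(rows, cols, bands)``.  Band-last is the canonical
        internal layout; readers transpose into it regardless of the on-disk
        interleave.
    wavelengths:
        Band-centre wavelengths in nanometres, strictly increasing, one per
        band.
    interleave:
        Preferred on-disk interleave (``"bil"``, ``"bip"`` or ``"bsq"``).
        Only consulted when writing.
    scale:
        ``"digital_number"`` for raw sensor counts, ``"reflectance"`` for
        calibrated data.  Reflectance cubes with values outside ``[0, 1.2]``
        are flagged (counted in :attr:`meta`) but never rejected — specular
        pixels routinely exceed the white reference.
    meta:
        Free-form metadata.  ``read_envi`` stores unrecognised header keys
        here under ``"envi_header"``; ``calibrate`` records its degenerate
        pixel count.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    interleave: str = "bil"
    scale: str = "reflectance"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D (rows, cols, bands), got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.data.shape[2]:
            raise ValueError(
                f"wavelength vector length {self.wavelengths.size} does not match "
                f"band axis {self.data.shape[2]}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.interleave not in _INTERLEAVES:
            raise ValueError(f"interleave must be one of {_INTERLEAVES}, got {self.interleave!r}")
        if self.scale not in ("digital_number", "reflectance"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "reflectance" and np.issubdtype(self.data.dtype, np.floating):
            finite = self.data[~np.isnan(self.data)]
            if finite.size and not np.all(np.isfinite(finite)):
                raise ValueError("reflectance cube contains non-finite (inf) values")
            n_out = int(np.sum((finite < 0.0) | (finite > 1.2)))
            if n_out:
                self.meta.setdefault("n_out_of_range", n_out)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


def _parse_header(text: str, path: Path) -> dict:
    """Parse an ENVI header into an ordered ``{key: value-string}`` dict."""
    stripped = text.lstrip()
    if not stripped.startswith("ENVI"):
        raise EnviFormatError(f"{path}: missing 'ENVI' magic line")
    body = stripped[4:]
    entries: dict[str, str] = {}
    i, n = 0, len(body)
    while i < n:
        eq = body.find("=", i)
        if eq < 0:
            break
        key = body[i:eq].strip().lower()
        j = eq + 1
        while j < n and body[j] in " \t":
            j += 1
        if j < n and body[j] == "{":
            close = body.find("}", j)
            if close < 0:
                raise EnviFormatError(f"{path}: unterminated '{{' for key {key!r}")
            value = body[j + 1 : close].strip()
            i = close + 1
        else:
            eol = body.find("\n", j)
            if eol < 0:
                eol = n
            value = body[j:eol].strip()
            i = eol + 1
        if key:
            entries[key] = value
    return entries


def _find_data_file(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    for cand in (stem, stem.with_suffix(".dat"), stem.with_suffix(".img"), stem.with_suffix(".raw")):
        if cand.exists() and cand != header_path:
            return cand
    raise FileNotFoundError(f"no data file found next to {header_path}")


def read_envi(header_path: str | Path) -> HyperCube:
    """Read an ENVI header/data pair into a band-last :class:`HyperCube`.

    Raises
    ------
    EnviFormatError
        If the ``wavelength`` block is absent (the error names the missing
        header key) or the data file size disagrees with the declared
        dimensions (the error reports both geometries).
    """
    header_path = Path(header_path)
    entries = _parse_header(header_path.read_text(), header_path)

    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in entries:
            raise EnviFormatError(f"{header_path}: required header key {key!r} missing")
    if "wavelength" not in entries:
        raise EnviFormatError(f"{header_path}: header key 'wavelength' missing — no wavelength axis")

    cols = int(entries["samples"])
    rows = int(entries["lines"])
    bands = int(entries["bands"])
    code = int(entries["data type"])
    if code not in _ENVI_DTYPES:
        raise EnviFormatError(f"{header_path}: unsupported ENVI data type code {code}")
    dtype = _ENVI_DTYPES[code]
    interleave = entries["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"{header_path}: unsupported interleave {interleave!r}")
    byte_order = int(entries.get("byte order", "0"))
    offset = int(entries.get("header offset", "0"))

    wavelengths = np.array([float(v) for v in entries["wavelength"].replace("\n", " ").split(",") if v.strip()])
    if wavelengths.size != bands:
        raise EnviFormatError(
            f"{header_path}: wavelength list has {wavelengths.size} entries for {bands} bands"
        )

    data_path = _find_data_file(header_path)
    expected = rows * cols * bands * dtype.itemsize + offset
    actual = data_path.stat().st_size
    if actual != expected:
        raise EnviFormatError(
            f"{data_path}: dimension mismatch — header declares (lines={rows}, samples={cols}, "
            f"bands={bands}) => {expected} bytes, file holds {actual} bytes"
        )

    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    if byte_order == 1:
        raw = raw.view(raw.dtype.newbyteorder(">")).astype(dtype)
    if interleave == "bsq":
        cube = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bip
        cube = raw.reshape(rows, cols, bands)

    known = {
        "samples", "lines", "bands", "data type", "interleave", "byte order",
        "header offset", "wavelength", "file type", "wavelength units",
    }
    extra = {k: v for k, v in entries.items() if k not in known}
    meta = {"envi_header": extra} if extra else {}
    scale = entries.get("scale", "reflectance" if np.issubdtype(dtype, np.floating) else "digital_number")
    if scale not in ("digital_number", "reflectance"):
        scale = "reflectance"
    return HyperCube(np.ascontiguousarray(cube), wavelengths, interleave=interleave, scale=scale, meta=meta)


def write_envi(cube: HyperCube, header_path: str | Path) -> tuple[Path, Path]:
    """Write ``cube`` as an ENVI ``.hdr``/``.dat`` pair.

    The raster is laid out in ``cube.interleave`` order; the round-trip
    through :func:`read_envi` is bit-exact for the cube's dtype.  Returns the
    header and data paths.
    """
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(".hdr")
    data_path = header_path.with_suffix(".dat")

    dtype = cube.data.dtype
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"dtype {dtype} has no ENVI type code; cast the cube first")
    rows, cols, bands = cube.data.shape

    if cube.interleave == "bsq":
        ondisk = cube.data.transpose(2, 0, 1)
    elif cube.interleave == "bil":
        ondisk = cube.data.transpose(0, 2, 1)
    else:
        ondisk = cube.data

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        "description = {gingerspec hyperspectral cube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[dtype]}",
        f"interleave = {cube.interleave}",
        "byte order = 0",
        f"scale = {cube.scale}",
        "wavelength units = Nanometers",
        f"wavelength = {{{wl}}}",
    ]
    for key, value in cube.meta.get("envi_header", {}).items():
        lines.append(f"{key} = {{{value}}}" if ("," in str(value) or "\n" in str(value)) else f"{key} = {value}")

    try:
        header_path.write_text("\n".join(lines) + "\n")
        np.ascontiguousarray(ondisk).tofile(data_path)
    except OSError as exc:
        raise OSError(f"cannot write ENVI pair at {header_path}: {exc}") from exc
    return header_path, data_path
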