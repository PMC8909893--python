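"""Reflectance calibration, ROI cropping and mean-spectrum extraction.

Raw hyperspectral frames are digital numbers (DN) shaped by the lamp
spectrum, the sensor gain and the dark current.  The standard flat-field
correction converts them to relative reflectance with a white-reference
frame (a high-reflectance ceramic tile) and a dark frame (shutter closed):

    I_c = (I_raw - I_dark) / (I_white - I_dark)

applied element-wise per pixel and band.  The tile's nominal 99% reflectance
factor is deliberately not divided out: the constant is absorbed by the
downstream regression, and the correction is implemented exactly as written.

After calibration a rectangular region of interest (ROI) over the sample is
cropped and its pixel spectra averaged into one spectrum per sample — the
unit all downstream modelling consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hsi_io import HyperCube

__all__ = [
    "ROI",
    "Spectrum",
    "CalibrationFrames",
    "calibrate",
    "crop_roi",
    "mean_spectrum",
]


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest; 0-based, half-open pixel intervals."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if self.row_end <= self.row_start or self.col_end <= self.col_start:
            raise ValueError(f"empty ROI: {self}")
        if min(self.row_start, self.col_start) < 0:
            raise ValueError(f"negative ROI indices: {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_end - self.row_start, self.col_end - self.col_start)


@dataclass
class Spectrum:
    """A single reflectance spectrum with its wavelength axis (nm)."""

    values: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.shape != self.wavelengths.shape or self.values.ndim != 1:
            raise ValueError("spectrum values and wavelengths must be 1-D and equally long")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite values")


def _frame_array(frame, raw: HyperCube, name: str) -> np.ndarray:
    """Return ``frame`` as float array broadcastable against ``raw.data``."""
    if isinstance(frame, HyperCube):
        if frame.n_bands != raw.n_bands or not np.allclose(frame.wavelengths, raw.wavelengths):
            raise ValueError(
                f"{name} frame wavelength axis ({frame.n_bands} bands) does not match "
                f"raw cube ({raw.n_bands} bands)"
            )
        arr = np.asarray(frame.data, dtype=float)
    else:
        arr = np.asarray(frame, dtype=float)
        if arr.ndim == 1:  # per-band vector
            arr = arr[None, None, :]
        if arr.shape[-1] != raw.n_bands:
            raise ValueError(f"{name} frame has {arr.shape[-1]} bands, raw cube has {raw.n_bands}")
    try:
        np.broadcast_shapes(arr.shape, raw.data.shape)
    except ValueError as exc:
        raise ValueError(f"{name} frame shape {arr.shape} not broadcastable to raw {raw.data.shape}") from exc
    return arr


@dataclass
class CalibrationFrames:
    """White and dark reference frames.

    Either member may be a full :class:`HyperCube`, a spatially reduced frame
    (e.g. one row per band, as pushbroom sensors record), or a plain
    per-band vector; everything broadcastable against the raw cube works.
    """

    white: object
    dark: object

    def validate_against(self, raw: HyperCube) -> tuple[np.ndarray, np.ndarray]:
        white = _frame_array(self.white, raw, "white")
        dark = _frame_array(self.dark, raw, "dark")
        w, d = np.broadcast_arrays(white, dark)
        frac = np.mean(w > d)
        if frac < 0.99:
            warnings.warn(
                f"calibration frames suspect: white > dark on only {frac:.1%} of pixels",
                stacklevel=3,
            )
        return white, dark


def calibrate(raw: HyperCube, frames: CalibrationFrames, eps: float = 1e-10) -> HyperCube:
    """Flat-field the raw cube to relative reflectance.

    Pixels whose denominator ``|white - dark|`` falls below ``eps`` cannot be
    corrected; they are set to NaN (the missing-value sentinel excluded by
    :func:`mean_spectrum`) and counted in the output's
    ``meta["n_degenerate"]``.  More than 1% degenerate pixels triggers a
    warning.
    """
    white, dark = frames.validate_against(raw)
    denom = white - dark
    bad = np.broadcast_to(np.abs(denom) < eps, raw.data.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (np.asarray(raw.data, dtype=float) - dark) / denom
    n_bad = int(bad.sum())
    if n_bad:
        refl = np.where(bad, np.nan, refl)
        if n_bad > 0.01 * raw.data.size:
            warnings.warn(f"{n_bad} degenerate calibration denominators (> 1% of pixels)", stacklevel=2)
    return HyperCube(
        refl,
        raw.wavelengths.copy(),
        interleave=raw.interleave,
        scale="reflectance",
        meta={**raw.meta, "n_degenerate": n_bad},
    )


def crop_roi(cube: HyperCube, roi: ROI) -> HyperCube:
    """Crop the spatial window ``roi``; the band axis is untouched."""
    rows, cols, _ = cube.shape
    if roi.row_end > rows or roi.col_end > cols:
        raise ValueError(f"ROI {roi} exceeds cube spatial extent ({rows} x {cols})")
    sub = cube.data[roi.row_start : roi.row_end, roi.col_start : roi.col_end, :]
    return HyperCube(sub.copy(), cube.wavelengths.copy(), interleave=cube.interleave,
                     scale=cube.scale, meta=dict(cube.meta))


def mean_spectrum(cube: HyperCube) -> Spectrum:
    """Average all spatial pixels into one spectrum, band by band.

    NaN pixels (degenerate-calibration sentinels) are excluded per band; a
    band with no valid pixel at all is an error naming that band.
    """
    data = np.asarray(cube.data, dtype=float)
    flat = data.reshape(-1, cube.n_bands)
    valid = ~np.isnan(flat)
    counts = valid.sum(axis=0)
    if np.any(counts == 0):
        band = int(np.argmax(counts == 0))
        raise ValueError(
            f"band {band} ({cube.wavelengths[band]:.2f} nm) has zero valid pixels in the ROI"
        )
    with np.errstate(invalid="ignore"):
        means = np.nansum(flat, axis=0) / counts
    return Spectrum(means, cube.wavelengths.copy())
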