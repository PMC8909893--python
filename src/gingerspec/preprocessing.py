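"""Spectral pre-treatments applied to the sample x band matrix.

Averaged reflectance spectra still carry artifacts that are not chemistry:
baseline offsets, multiplicative light-scattering differences between
powdered samples, and residual random noise.  Seven classical treatments
address them, each a pure function of the ``N x K`` spectra matrix:

=========  ==========================================================
tag        treatment
=========  ==========================================================
``raw``    identity (untreated averaged spectra)
``snv``    standard normal variate — per-spectrum centre/scale
``msc``    multiplicative scatter correction against a reference
``mf5``    1-D moving average along the band axis, width 5
``mf9``    width-9 moving average
``mf11``   width-11 moving average
``sg1``    Savitzky–Golay first derivative (per nm)
``sg2``    Savitzky–Golay second derivative (per nm)
=========  ==========================================================

The mean filters act on the band axis of the averaged spectra (treatments
are applied after ROI averaging); an optional per-band *spatial* mean filter
on the cube is provided separately for the alternative reading in which the
window is a 2-D image kernel.

MSC is the one stateful treatment: its reference spectrum is the training
set column mean, fitted once and then applied frozen to test spectra so no
test information leaks into the correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import convolve1d, uniform_filter
from scipy.signal import savgol_filter

from .hsi_io import HyperCube

__all__ = [
    "SpectraMatrix",
    "MscReference",
    "snv",
    "msc_fit",
    "msc_apply",
    "mean_filter",
    "savgol_derivative",
    "spatial_mean_filter",
    "Treatment",
    "make_treatment",
    "CANONICAL_TREATMENTS",
]

#: The canonical eight-variant treatment grid: untreated spectra plus the
#: named treatments, with the three moving-average widths enumerated
#: separately and the two Savitzky–Golay derivative orders separately.
CANONICAL_TREATMENTS = ("raw", "snv", "msc", "mf5", "mf9", "mf11", "sg1", "sg2")


@dataclass
class SpectraMatrix:
    """``N x K`` spectra with wavelength axis and a provenance tag."""

    X: np.ndarray
    wavelengths: np.ndarray
    treatment_tag: str = "raw"

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.X.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"matrix has {self.X.shape[1]} bands but wavelength axis has {self.wavelengths.size}"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("spectra matrix contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]


def _unwrap(X):
    if isinstance(X, SpectraMatrix):
        return X.X, X
    return np.atleast_2d(np.asarray(X, dtype=float)), None


def _rewrap(out: np.ndarray, parent, tag: str):
    if parent is None:
        return out
    return SpectraMatrix(out, parent.wavelengths.copy(), treatment_tag=tag)


def snv(X):
    """Standard normal variate: each spectrum to mean 0, sample SD 1.

    The SD uses the unbiased ``K - 1`` denominator, so ``[1, 2, 3]`` maps to
    ``[-1, 0, 1]`` exactly.  A zero-variance spectrum cannot be scaled and is
    an error naming the offending sample.
    """
    arr, parent = _unwrap(X)
    sd = arr.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise ValueError(f"sample {bad} has zero spectral variance; SNV undefined")
    out = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    return _rewrap(out, parent, "snv")


@dataclass
class MscReference:
    """Frozen MSC state: the reference spectrum and the last fitted lines."""

    reference_spectrum: np.ndarray
    slopes: np.ndarray | None = None
    intercepts: np.ndarray | None = None


def msc_fit(X_train) -> MscReference:
    """Fit the MSC reference spectrum (column mean of the training set)."""
    arr, _ = _unwrap(X_train)
    if arr.shape[0] < 2:
        raise ValueError("MSC needs at least 2 training spectra to form a reference")
    return MscReference(arr.mean(axis=0))


def msc_apply(X, ref: MscReference):
    """Regress each spectrum on the reference and invert the fitted line.

    For spectrum ``x``, ordinary least squares fits
    ``x ~ slope * reference + intercept``; the corrected spectrum is
    ``(x - intercept) / slope``, undoing additive offset and multiplicative
    scatter in one step.  Near-zero slopes (|slope| < 1e-8) make the
    inversion meaningless and raise, naming the sample.
    """
    arr, parent = _unwrap(X)
    r = np.asarray(ref.reference_spectrum, dtype=float)
    if r.size != arr.shape[1]:
        raise ValueError(f"reference has {r.size} bands, spectra have {arr.shape[1]}")
    rc = r - r.mean()
    denom = rc @ rc
    if denom == 0:
        raise ValueError("MSC reference spectrum is constant; slope undefined")
    slopes = (arr - arr.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(np.abs(slopes) < 1e-8):
        bad = int(np.argmax(np.abs(slopes) < 1e-8))
        raise ValueError(f"sample {bad}: fitted MSC slope ~ 0; correction undefined")
    intercepts = arr.mean(axis=1) - slopes * r.mean()
    out = (arr - intercepts[:, None]) / slopes[:, None]
    ref.slopes, ref.intercepts = slopes, intercepts
    return _rewrap(out, parent, "msc")


def mean_filter(X, width: int):
    """Centered moving average of each spectrum along the band axis.

    Edge windows are truncated to in-range bands (the average is taken over
    however much of the window exists), so a constant spectrum is exactly
    invariant.  ``width`` must be odd and no larger than the band count.
    """
    arr, parent = _unwrap(X)
    k = arr.shape[1]
    if width % 2 == 0:
        raise ValueError(f"mean filter width must be odd, got {width}")
    if not 1 <= width <= k:
        raise ValueError(f"width {width} outside [1, {k}]")
    kernel = np.ones(width)
    sums = convolve1d(arr, kernel, axis=1, mode="constant", cval=0.0)
    counts = convolve1d(np.ones(k), kernel, mode="constant", cval=0.0)
    out = sums / counts
    return _rewrap(out, parent, f"mf{width}")


def savgol_derivative(X, deriv_order: int, window: int = 11, polyorder: int | None = None,
                      delta: float | None = None):
    """Savitzky–Golay derivative of each spectrum.

    A local polynomial of degree ``polyorder`` is least-squares fitted in a
    sliding ``window`` and differentiated ``deriv_order`` times; the result
    is exact on polynomials of degree <= ``polyorder``.  When ``X`` is a
    :class:`SpectraMatrix` the derivative is expressed per nanometre using
    the (uniform) band spacing; for a bare array, ``delta`` defaults to one
    band index.  Defaults: polyorder 2 for the first derivative, 3 for the
    second.
    """
    arr, parent = _unwrap(X)
    if polyorder is None:
        polyorder = 2 if deriv_order == 1 else 3
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if polyorder >= window:
        raise ValueError(f"polyorder ({polyorder}) must be < window ({window})")
    if deriv_order > polyorder:
        raise ValueError(f"deriv_order ({deriv_order}) must be <= polyorder ({polyorder})")
    if window > arr.shape[1]:
        raise ValueError(f"window ({window}) exceeds band count ({arr.shape[1]})")
    if delta is None:
        if parent is not None and parent.wavelengths.size > 1:
            delta = float(np.mean(np.diff(parent.wavelengths)))
        else:
            delta = 1.0
    out = savgol_filter(arr, window_length=window, polyorder=polyorder,
                        deriv=deriv_order, delta=delta, axis=1, mode="interp")
    return _rewrap(out, parent, f"sg{deriv_order}")


def spatial_mean_filter(cube: HyperCube, size: int) -> HyperCube:
    """Per-band 2-D mean filter on the image plane (the alternative reading
    of an ``n x n`` mean-filter window, applied before ROI averaging)."""
    if size % 2 == 0:
        raise ValueError(f"spatial filter size must be odd, got {size}")
    out = uniform_filter(np.asarray(cube.data, dtype=float), size=(size, size, 1), mode="nearest")
    return HyperCube(out, cube.wavelengths.copy(), interleave=cube.interleave,
                     scale=cube.scale, meta=dict(cube.meta))


class Treatment:
    """A named pre-treatment with scikit-learn-style fit/transform discipline.

    Stateless treatments ignore :meth:`fit`; MSC learns its reference there.
    """

    def __init__(self, name: str, func, stateful: bool = False, **params):
        self.name = name
        self._func = func
        self._stateful = stateful
        self.params = params
        self._state = None

    def fit(self, X_train) -> "Treatment":
        if self._stateful:
            self._state = msc_fit(X_train)
        return self

    def transform(self, X):
        if self._stateful:
            if self._state is None:
                raise RuntimeError(f"treatment {self.name!r} must be fitted before transform")
            return msc_apply(X, self._state)
        return self._func(X, **self.params)

    def fit_transform(self, X_train):
        return self.fit(X_train).transform(X_train)


def make_treatment(name: str, sg_window: int = 11, sg_polyorder_first: int = 2,
                   sg_polyorder_second: int = 3) -> Treatment:
    """Build a :class:`Treatment` from its canonical tag (see module docs)."""
    name = name.lower()
    if name in ("raw", "none"):
        return Treatment("raw", _identity)
    if name == "snv":
        return Treatment("snv", snv)
    if name == "msc":
        return Treatment("msc", None, stateful=True)
    if name.startswith("mf"):
        width = int(name[2:])
        return Treatment(name, mean_filter, width=width)
    if name == "sg1":
        return Treatment("sg1", savgol_derivative, deriv_order=1,
                         window=sg_window, polyorder=sg_polyorder_first)
    if name == "sg2":
        return Treatment("sg2", savgol_derivative, deriv_order=2,
                         window=sg_window, polyorder=sg_polyorder_second)
    raise ValueError(f"unknown treatment {name!r}; known: {CANONICAL_TREATMENTS}")


def _identity(X):
    arr, parent = _unwrap(X)
    return _rewrap(arr.copy(), parent, "raw")
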