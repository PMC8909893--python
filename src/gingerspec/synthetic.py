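"""Synthetic hyperspectral ginger datasets with known ground truth.

The real study substrate — dried ginger powder imaged by a pushbroom
Vis-NIR camera, with 6-gingerol and 6-shogaol contents assayed by HPLC —
is not publicly archived.  This module generates a stand-in with the same
statistical structure, so every downstream stage (calibration,
pre-processing, regression, wavelength selection, evaluation) is testable
against known truth.

Forward model
-------------
Each sample carries true constituent concentrations (mg/g) drawn from a
log-normal law.  Its pure reflectance spectrum is a smooth baseline minus
Beer–Lambert-like Gaussian absorption features, one set per constituent:

    r(λ) = baseline(λ) - Σ_i c_i Σ_k w_k exp(-((λ - μ_k)² / 2σ_k²)),

clipped to [0.02, 0.98].  The camera then observes, per pixel,

    DN(λ) = gain(λ) · (a·r(λ) + b) + dark(λ) + ε·gain(λ),

where ``a ~ N(1, scatter_multiplicative_sd)`` and
``b ~ N(0, scatter_additive_sd)`` are drawn once per sample (packing and
surface geometry differ between samples, not between neighbouring pixels of
one powder bed) and ``ε ~ N(0, pixel_noise_sd)`` independently per pixel and
band.  These are exactly the artifact classes the spectral pre-treatments
exist to remove: multiplicative scatter, baseline shift, random noise.
The white frame is ``gain + dark`` (a perfect reflector) and the dark frame
``dark``, so flat-field calibration recovers ``a·r + b`` up to pixel noise.

Concentration law
-----------------
Real concentration distributions for the study material are not published
numerically.  The default law reflects the chemistry — 6-shogaol is the
dehydration product of 6-gingerol, so the two are correlated:
``shogaol ~ LogNormal(ln 1.8 mg/g, 0.12)``, the ratio
``ρ ~ LogNormal(ln 1.5, 0.45)`` and ``gingerol = ρ · shogaol``.  The ratio
then spans roughly 0.5–4, wide enough that limits of detection near 0.6–1.0
fall inside the data range.  All of this is configuration, not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import Spectrum
from .hsi_io import HyperCube, write_envi

__all__ = [
    "ConcentrationLaw",
    "SyntheticConfig",
    "SyntheticSample",
    "generate_dataset",
    "write_reference_table",
    "read_reference_table",
    "write_dataset",
    "DEFAULT_CONSTITUENT_BANDS",
]

#: Gaussian absorption features (centre nm, width nm, weight per mg/g) per
#: constituent.  Centres are distinct between constituents so the two band
#: sets are non-collinear and the ratio is identifiable from the spectrum.
DEFAULT_CONSTITUENT_BANDS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "gingerol": ((670.0, 35.0, 0.018), (915.0, 55.0, 0.022)),
    "shogaol": ((560.0, 30.0, 0.020), (985.0, 45.0, 0.028)),
}


@dataclass
class ConcentrationLaw:
    """Log-normal law for constituent concentrations (mg/g).

    The shogaol content and the gingerol:shogaol ratio are drawn
    independently; gingerol follows as their product.
    """

    shogaol_median: float = 1.8
    shogaol_sigma: float = 0.12
    ratio_median: float = 1.5
    ratio_sigma: float = 0.45

    def draw(self, rng: np.random.Generator) -> tuple[float, float]:
        """Return one (gingerol, shogaol) pair; non-positive draws (possible
        only with degenerate parameters) are rejected and redrawn."""
        for _ in range(1000):
            shogaol = float(rng.lognormal(np.log(self.shogaol_median), self.shogaol_sigma))
            ratio = float(rng.lognormal(np.log(self.ratio_median), self.ratio_sigma))
            gingerol = ratio * shogaol
            if gingerol > 0 and shogaol > 0:
                return gingerol, shogaol
        raise RuntimeError("concentration law failed to produce positive draws")


@dataclass
class SyntheticConfig:
    """Everything that defines one simulated acquisition campaign."""

    n_samples: int = 89
    n_bands: int = 204
    wavelength_start: float = 397.32
    wavelength_end: float = 1003.58
    cube_rows: int = 64
    cube_cols: int = 64
    constituent_bands: dict = field(default_factory=lambda: {
        k: tuple(v) for k, v in DEFAULT_CONSTITUENT_BANDS.items()
    })
    concentration_law: ConcentrationLaw = field(default_factory=ConcentrationLaw)
    scatter_multiplicative_sd: float = 0.05
    scatter_additive_sd: float = 0.02
    pixel_noise_sd: float = 0.01
    seed: int = 0
    dtype: str = "float32"    # DN storage; use float64 for exactness studies

    def __post_init__(self) -> None:
        if self.n_bands < 4:
            raise ValueError("need at least 4 bands")
        if self.wavelength_end <= self.wavelength_start:
            raise ValueError("wavelength axis must be increasing")
        if min(self.n_samples, self.cube_rows, self.cube_cols) < 1:
            raise ValueError("sample count and cube shape must be positive")
        for name, sd in (
            ("scatter_multiplicative_sd", self.scatter_multiplicative_sd),
            ("scatter_additive_sd", self.scatter_additive_sd),
            ("pixel_noise_sd", self.pixel_noise_sd),
        ):
            if sd < 0:
                raise ValueError(f"{name} must be >= 0")
        if isinstance(self.concentration_law, dict):
            self.concentration_law = ConcentrationLaw(**self.concentration_law)

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wavelength_start, self.wavelength_end, self.n_bands)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["constituent_bands"] = {k: [list(b) for b in v] for k, v in d["constituent_bands"].items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "constituent_bands" in d:
            d["constituent_bands"] = {k: tuple(tuple(b) for b in v)
                                      for k, v in d["constituent_bands"].items()}
        return cls(**d)


@dataclass
class SyntheticSample:
    """One simulated acquisition with its ground truth."""

    sample_id: str
    raw_cube: HyperCube           # digital numbers
    white_frame: HyperCube        # shared instrument frame, (1, 1, bands)
    dark_frame: HyperCube
    true_reflectance: Spectrum    # pure r(λ), before scatter and noise
    gingerol_conc: float          # mg/g
    shogaol_conc: float           # mg/g
    ratio: float
    scatter_a: float = 1.0        # per-sample multiplicative scatter actually drawn
    scatter_b: float = 0.0        # per-sample additive offset


def _baseline(wl: np.ndarray) -> np.ndarray:
    # gentle powder-like reflectance: darker in the blue, flat in the NIR
    return 0.72 - 0.15 * np.exp(-(((wl - 450.0) / 120.0) ** 2))


def _gain(wl: np.ndarray) -> np.ndarray:
    # smooth instrument response, DN scale ~ 1200-2500
    return 2500.0 * (0.5 + 0.5 * np.exp(-(((wl - 720.0) / 260.0) ** 2)))


def _dark(wl: np.ndarray) -> np.ndarray:
    return 96.0 + 0.01 * (wl - wl[0])


def pure_reflectance(config: SyntheticConfig, gingerol: float, shogaol: float) -> np.ndarray:
    """The noise-free reflectance spectrum for one concentration pair."""
    wl = config.wavelengths
    r = _baseline(wl).copy()
    conc = {"gingerol": gingerol, "shogaol": shogaol}
    for name, bands in config.constituent_bands.items():
        c = conc.get(name, 0.0)
        for center, width, weight in bands:
            r -= c * weight * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return np.clip(r, 0.02, 0.98)


def generate_dataset(config: SyntheticConfig = SyntheticConfig()) -> list[SyntheticSample]:
    """Simulate the full campaign: one raw DN cube per sample plus the
    shared white/dark frames.  Deterministic for a fixed ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths
    gain = _gain(wl)
    dark = _dark(wl)
    dtype = np.dtype(config.dtype)

    white = HyperCube((gain + dark)[None, None, :].astype(dtype), wl,
                      scale="digital_number")
    dark_cube = HyperCube(dark[None, None, :].astype(dtype), wl,
                          scale="digital_number")

    samples: list[SyntheticSample] = []
    for i in range(config.n_samples):
        gingerol, shogaol = config.concentration_law.draw(rng)
        r = pure_reflectance(config, gingerol, shogaol)
        a = 1.0 + rng.normal(0.0, config.scatter_multiplicative_sd) if config.scatter_multiplicative_sd else 1.0
        b = rng.normal(0.0, config.scatter_additive_sd) if config.scatter_additive_sd else 0.0
        signal = gain * (a * r + b) + dark
        if config.pixel_noise_sd:
            eps = rng.normal(0.0, config.pixel_noise_sd,
                             size=(config.cube_rows, config.cube_cols, config.n_bands))
            dn = signal[None, None, :] + eps * gain[None, None, :]
        else:
            dn = np.broadcast_to(signal, (config.cube_rows, config.cube_cols, config.n_bands)).copy()
        samples.append(SyntheticSample(
            sample_id=f"S{i:03d}",
            raw_cube=HyperCube(dn.astype(dtype), wl, scale="digital_number"),
            white_frame=white,
            dark_frame=dark_cube,
            true_reflectance=Spectrum(r, wl),
            gingerol_conc=gingerol,
            shogaol_conc=shogaol,
            ratio=gingerol / shogaol,
            scatter_a=a,
            scatter_b=b,
        ))
    return samples


def write_reference_table(samples: list[SyntheticSample], path: str | Path) -> Path:
    """CSV of per-sample reference values: sample_id, gingerol, shogaol, ratio.

    Values are written at 6 decimals; reading the table back reproduces the
    in-memory values at that precision.  Duplicate sample ids are an error.
    """
    if not samples:
        raise ValueError("no samples to write")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
    df = pd.DataFrame({
        "sample_id": ids,
        "gingerol": [s.gingerol_conc for s in samples],
        "shogaol": [s.shogaol_conc for s in samples],
        "ratio": [s.ratio for s in samples],
    })
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_reference_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_dataset(samples: list[SyntheticSample], outdir: str | Path,
                  config: SyntheticConfig | None = None) -> Path:
    """Persist a campaign: one ENVI pair per sample, the shared white/dark
    frames, the reference CSV and (optionally) the config as YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in samples:
        write_envi(s.raw_cube, outdir / f"{s.sample_id}.hdr")
    if samples:
        write_envi(samples[0].white_frame, outdir / "white.hdr")
        write_envi(samples[0].dark_frame, outdir / "dark.hdr")
    write_reference_table(samples, outdir / "reference.csv")
    if config is not None:
        config.to_yaml(outdir / "config.yaml")
    return outdir
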