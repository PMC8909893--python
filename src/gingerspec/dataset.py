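"""The sample x band container consumed by the regression models."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import SpectraMatrix

__all__ = ["SpectralDataset"]


@dataclass
class SpectralDataset:
    """Paired spectra matrix and response vector.

    ``X`` holds one (pre-processed or raw) mean spectrum per sample; ``y``
    is the 6-gingerol : 6-shogaol ratio.  The response is always the ratio,
    never the individual concentrations.
    """

    X: np.ndarray
    wavelengths: np.ndarray
    y: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    treatment_tag: str = "raw"

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape != (self.y.size, self.wavelengths.size):
            raise ValueError(
                f"inconsistent dataset: X {self.X.shape}, y {self.y.size}, "
                f"wavelengths {self.wavelengths.size}"
            )
        if not self.sample_ids:
            self.sample_ids = [f"S{i:03d}" for i in range(self.y.size)]
        if len(self.sample_ids) != self.y.size:
            raise ValueError("sample_ids length does not match sample count")

    @property
    def n_samples(self) -> int:
        return self.y.size

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    @property
    def spectra(self) -> SpectraMatrix:
        return SpectraMatrix(self.X, self.wavelengths, treatment_tag=self.treatment_tag)

    def subset(self, indices) -> "SpectralDataset":
        idx = np.asarray(indices, dtype=int)
        return SpectralDataset(
            self.X[idx], self.wavelengths.copy(), self.y[idx],
            [self.sample_ids[i] for i in idx], self.treatment_tag,
        )

    def with_spectra(self, spectra: SpectraMatrix) -> "SpectralDataset":
        """Same samples, new (treated) spectra."""
        return SpectralDataset(spectra.X, spectra.wavelengths.copy(), self.y.copy(),
                               list(self.sample_ids), spectra.treatment_tag)

    def to_csv(self, path: str | Path) -> None:
        """Wide CSV: sample_id, ratio, then one column per wavelength."""
        cols = {f"{w:.4f}": self.X[:, j] for j, w in enumerate(self.wavelengths)}
        df = pd.DataFrame({"sample_id": self.sample_ids, "ratio": self.y, **cols})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralDataset":
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if c not in ("sample_id", "ratio")]
        return cls(
            df[wl_cols].to_numpy(float), np.array([float(c) for c in wl_cols]),
            df["ratio"].to_numpy(float), df["sample_id"].astype(str).tolist(),
        )
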