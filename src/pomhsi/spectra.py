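"""The per-sample spectrum table: ROI-averaged spectra plus labels.

This is the feature matrix handed from image processing to chemometrics:
one row per fruit sample (the mean reflectance spectrum over its region of
interest), one column per wavelength, with a class label and sample id per
row.  Serialized as CSV with columns ``sample_id,label,<wavelength...>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ConfigurationError, ShapeError

__all__ = ["SpectrumTable"]


@dataclass
class SpectrumTable:
    X: np.ndarray  # (n_samples, n_bands)
    wavelengths: np.ndarray  # (n_bands,) in nm
    labels: list[str]
    sample_ids: list[str]
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.X.ndim != 2:
            raise ShapeError("spectrum matrix must be 2-D (samples x bands)")
        if self.X.shape[1] != len(self.wavelengths):
            raise ShapeError("column count must equal wavelength count")
        if self.X.shape[0] != len(self.labels) or self.X.shape[0] != len(self.sample_ids):
            raise ShapeError("row count must equal label and id counts")
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise ConfigurationError("spectrum table contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def with_values(self, X: np.ndarray, step: str | None = None) -> "SpectrumTable":
        """Same rows/labels with a new value matrix (post-transform)."""
        hist = list(self.history) + ([step] if step else [])
        return SpectrumTable(X, self.wavelengths.copy(), list(self.labels), list(self.sample_ids), hist)

    def take_rows(self, idx: Sequence[int], step: str | None = None) -> "SpectrumTable":
        idx = np.asarray(idx, dtype=int)
        hist = list(self.history) + ([step] if step else [])
        return SpectrumTable(
            self.X[idx],
            self.wavelengths.copy(),
            [self.labels[i] for i in idx],
            [self.sample_ids[i] for i in idx],
            hist,
        )

    def take_bands(self, band_idx: Sequence[int], step: str | None = None) -> "SpectrumTable":
        band_idx = np.asarray(band_idx, dtype=int)
        hist = list(self.history) + ([step] if step else [])
        return SpectrumTable(
            self.X[:, band_idx],
            self.wavelengths[band_idx],
            list(self.labels),
            list(self.sample_ids),
            hist,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"{w:.6g}" for w in self.wavelengths])
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectrumTable":
        df = pd.read_csv(path)
        if "sample_id" not in df.columns or "label" not in df.columns:
            raise ConfigurationError("spectrum CSV must have sample_id and label columns")
        wl_cols = [c for c in df.columns if c not in ("sample_id", "label")]
        wavelengths = np.array([float(c) for c in wl_cols])
        return cls(
            df[wl_cols].to_numpy(dtype=float),
            wavelengths,
            df["label"].astype(str).tolist(),
            df["sample_id"].astype(str).tolist(),
        )
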