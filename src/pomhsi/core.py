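"""Core containers for hyperspectral cubes and camera profiles.

A hyperspectral image is stored as a 3-D block indexed (line, sample, band),
i.e. ``values[y, x, k]`` where ``y`` runs along the translation-stage scan
direction, ``x`` along the detector line, and ``k`` along the spectral axis.
The band axis carries a strictly increasing wavelength grid in nanometres.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "CameraProfile",
    "HyperCube",
    "make_camera_profile",
    "ConfigurationError",
    "ShapeError",
]


class ConfigurationError(ValueError):
    """Invalid user-supplied configuration (unknown profile, bad parameter)."""


class ShapeError(ValueError):
    """Mismatched cube dimensions or wavelength grids."""


@dataclass(frozen=True)
class CameraProfile:
    """A line-scan hyperspectral camera: spectral range, sampling and depth.

    Parameters
    ----------
    name
        Identifier, e.g. ``"vnir"`` or ``"swir"``.
    lambda_min, lambda_max
        Spectral range endpoints in nm.
    n_bands
        Number of spectral channels; the wavelength grid is uniform over
        ``[lambda_min, lambda_max]`` inclusive.
    bit_depth
        Digitizer resolution; raw counts live in ``[0, 2**bit_depth - 1]``.
    """

    name: str
    lambda_min: float
    lambda_max: float
    n_bands: int
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.lambda_min < self.lambda_max:
            raise ConfigurationError(
                f"lambda_min ({self.lambda_min}) must be < lambda_max ({self.lambda_max})"
            )
        if self.n_bands < 2:
            raise ConfigurationError("a camera profile needs at least 2 bands")
        if self.bit_depth < 1:
            raise ConfigurationError("bit_depth must be positive")

    @property
    def wavelengths(self) -> np.ndarray:
        """Uniform, strictly increasing wavelength grid in nm."""
        return np.linspace(self.lambda_min, self.lambda_max, self.n_bands)

    @property
    def sampling_nm(self) -> float:
        return (self.lambda_max - self.lambda_min) / (self.n_bands - 1)

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1


#: Built-in camera profiles: VNIR 400-1000 nm / 186 channels and
#: SWIR 930-2500 nm / 288 channels, both 16-bit line-scan units.
BUILTIN_PROFILES: dict[str, CameraProfile] = {
    "vnir": CameraProfile("vnir", 400.0, 1000.0, 186, 16),
    "swir": CameraProfile("swir", 930.0, 2500.0, 288, 16),
}


def make_camera_profile(
    name: str,
    *,
    lambda_min: float | None = None,
    lambda_max: float | None = None,
    n_bands: int | None = None,
    bit_depth: int = 16,
) -> CameraProfile:
    """Return a built-in camera profile by name, or build a custom one.

    ``"vnir"`` and ``"swir"`` return the two built-in line-scan profiles.
    Any other name requires explicit ``lambda_min``, ``lambda_max`` and
    ``n_bands``.
    """
    key = name.lower()
    if key in BUILTIN_PROFILES:
        prof = BUILTIN_PROFILES[key]
        if n_bands is not None and n_bands != prof.n_bands:
            # channel count is exposed as a parameter (some acquisition modes
            # bin the spectral axis)
            return CameraProfile(key, prof.lambda_min, prof.lambda_max, n_bands, bit_depth)
        return prof
    if lambda_min is None or lambda_max is None or n_bands is None:
        raise ConfigurationError(
            f"unknown camera profile {name!r}; supply lambda_min/lambda_max/n_bands "
            "for a custom profile"
        )
    return CameraProfile(name, float(lambda_min), float(lambda_max), int(n_bands), bit_depth)


@dataclass
class HyperCube:
    """A 3-D hyperspectral block with wavelengths and provenance metadata.

    ``values`` has shape ``(lines, samples, bands)``; ``kind`` distinguishes
    raw digital counts from calibrated reflectance.  ``metadata`` carries
    free-form provenance; the ``"history"`` entry is an append-only list of
    processing steps.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    kind: str = "counts"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ShapeError(f"cube must be 3-D, got shape {self.values.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[2]:
            raise ShapeError(
                f"wavelength vector length {len(self.wavelengths)} does not match "
                f"band axis {self.values.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ShapeError("wavelengths must be strictly increasing")
        if self.kind not in ("counts", "reflectance"):
            raise ConfigurationError(f"unknown cube kind {self.kind!r}")
        self.metadata.setdefault("history", [])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def log(self, step: str, **info: Any) -> None:
        """Append a processing step to the cube's history."""
        self.metadata["history"].append({"step": step, **info})

    def copy(self) -> "HyperCube":
        return HyperCube(
            self.values.copy(),
            self.wavelengths.copy(),
            self.kind,
            copy.deepcopy(self.metadata),
        )

    def same_grid(self, other: "HyperCube") -> bool:
        return len(self.wavelengths) == len(other.wavelengths) and np.allclose(
            self.wavelengths, other.wavelengths
        )
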