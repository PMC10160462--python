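"""White/dark reference correction of raw count cubes to reflectance.

Per pixel and band the corrected reflectance is

    rho = rho_ref * (R_raw - R_dark) / (R_white - R_dark)

where ``rho_ref`` is the reflectivity of the grey calibration panel (0.5 for
a 50% panel, spectrally flat by default; a per-band vector is accepted).
This removes the uneven illumination of the light source and the detector's
dark current in one step.  Pixels whose white-dark denominator falls below a
configurable floor are flagged invalid and set to 0; values above
``clip_max`` are clipped, and both tallies are recorded in the output
metadata so downstream averaging can exclude flagged pixels.
"""

from __future__ import annotations

import numpy as np

from .core import ConfigurationError, HyperCube, ShapeError

__all__ = ["calibrate"]


def _broadcast_reference(
    ref: HyperCube, target_shape: tuple[int, int, int], dtype: np.dtype
) -> np.ndarray:
    """Broadcast a (possibly single-line) reference cube along the scan axis."""
    vals = ref.values.astype(dtype)
    if vals.shape == target_shape:
        return vals
    if vals.shape[0] == 1 and vals.shape[1:] == target_shape[1:]:
        return np.broadcast_to(vals, target_shape)
    raise ShapeError(
        f"reference shape {vals.shape} incompatible with raw shape {target_shape}"
    )


def calibrate(
    raw: HyperCube,
    white: HyperCube,
    dark: HyperCube,
    rho_ref: float | np.ndarray = 0.5,
    *,
    denominator_floor: float = 1.0,
    clip_max: float = 1.2,
) -> HyperCube:
    """Convert a raw count cube to reflectance using white/dark references.

    Parameters
    ----------
    raw, white, dark
        Count cubes sharing one wavelength grid.  White and dark may be
        single scan lines (first axis of length 1); they are broadcast.
    rho_ref
        Panel reflectivity: a scalar in (0, 1] or a per-band vector.
    denominator_floor
        Pixels with ``white - dark`` below this (in counts) are flagged
        invalid and set to 0 rather than producing unstable ratios.
    clip_max
        Upper clip for the corrected reflectance (values slightly above 1
        occur on specular pixels); the number of clipped values is recorded.

    Returns
    -------
    HyperCube
        Reflectance cube; ``metadata["invalid_mask"]`` is a boolean (lines,
        samples) image marking pixels with any flagged band, and
        ``metadata["n_invalid"]`` / ``metadata["n_clipped"]`` count flagged
        and clipped entries.
    """
    if raw.kind != "counts":
        raise ConfigurationError(
            f"raw cube has kind {raw.kind!r}; calibration expects digital counts"
        )
    for ref in (white, dark):
        if not raw.same_grid(ref):
            raise ShapeError("raw and reference cubes must share a wavelength grid")

    rho = np.asarray(rho_ref, dtype=float)
    if rho.ndim == 0:
        if not 0.0 < float(rho) <= 1.0:
            raise ConfigurationError(f"rho_ref must lie in (0, 1], got {float(rho)}")
    elif rho.ndim == 1:
        if len(rho) != raw.n_bands:
            raise ShapeError("per-band rho_ref length must equal the band count")
        if np.any(rho <= 0.0) or np.any(rho > 1.0):
            raise ConfigurationError("per-band rho_ref values must lie in (0, 1]")
    else:
        raise ConfigurationError("rho_ref must be a scalar or a per-band vector")

    # counts fit float32 exactly (< 2**24); float64 inputs keep full precision
    work = np.float64 if raw.values.dtype == np.float64 else np.float32
    raw_v = raw.values.astype(work)
    white_v = _broadcast_reference(white, raw.values.shape, work)
    dark_v = _broadcast_reference(dark, raw.values.shape, work)

    denom = white_v - dark_v
    invalid = np.abs(denom) < denominator_floor
    np.subtract(raw_v, dark_v, out=raw_v)
    denom[invalid] = 1.0
    np.divide(raw_v, denom, out=raw_v)
    rho_out = rho * raw_v if np.ndim(rho) else np.multiply(raw_v, work(rho), out=raw_v)
    rho_out[invalid] = 0.0

    clipped = rho_out > clip_max
    n_clipped = int(np.count_nonzero(clipped))
    rho_out = np.clip(rho_out, None, clip_max)

    meta = {
        "rho_ref": rho.tolist() if rho.ndim else float(rho),
        "denominator_floor": denominator_floor,
        "clip_max": clip_max,
        "n_invalid": int(np.count_nonzero(invalid)),
        "n_clipped": n_clipped,
        "invalid_mask": invalid.any(axis=2),
        "history": list(raw.metadata.get("history", [])),
    }
    for key in ("profile", "seed", "severity"):
        if key in raw.metadata:
            meta[key] = raw.metadata[key]
    out = HyperCube(rho_out.astype(np.float32, copy=False), raw.wavelengths.copy(), "reflectance", meta)
    out.log("calibrate", rho_ref=meta["rho_ref"], floor=denominator_floor, clip_max=clip_max)
    return out
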