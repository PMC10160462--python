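"""Spectral preprocessing transforms for ROI-averaged spectra.

Seven variants are supported, matching common chemometric practice for
scatter and baseline correction of diffuse-reflectance spectra:

``raw``
    identity (no preprocessing);
``snv``
    standard normal variate — per-spectrum standardization to zero mean and
    unit (sample) standard deviation;
``msc``
    multiplicative scatter correction — per-spectrum affine regression
    against a reference spectrum (the set mean by default), inverted;
``detrend``
    subtraction of a least-squares polynomial in wavelength (order 2 by
    default);
``continuum_removal``
    division by the upper convex hull of the spectrum;
``sg1`` / ``sg2``
    Savitzky–Golay first and second derivatives.

All transforms are per-row; only MSC's default reference couples rows (it
is fit from the rows it is given, so fit it on training data and pass the
resulting reference when transforming held-out spectra).  Rows that cannot
be transformed (constant spectra for SNV, near-zero MSC slope, non-positive
values for continuum removal) are excluded from the output and reported on
the returned table's ``excluded`` attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import savgol_filter

from .core import ConfigurationError
from .spectra import SpectrumTable

__all__ = [
    "PreprocessSpec",
    "METHODS",
    "snv",
    "msc",
    "detrend",
    "continuum_removal",
    "savgol_derivative",
    "apply",
]

METHODS = ("raw", "snv", "msc", "detrend", "continuum_removal", "sg1", "sg2")


@dataclass
class PreprocessSpec:
    """A named preprocessing method plus its parameters."""

    method: str = "snv"
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(
                f"unknown preprocessing method {self.method!r}; choose from {METHODS}"
            )


def _finish(
    table: SpectrumTable,
    X: np.ndarray,
    keep: np.ndarray,
    step: str,
    dropped: list[tuple[str, str]],
) -> SpectrumTable:
    if keep.all():
        out = table.with_values(X, step=step)
    else:
        idx = np.flatnonzero(keep)
        out = table.take_rows(idx).with_values(X[idx], step=step)
    out.excluded = dropped  # type: ignore[attr-defined]
    return out


def snv(table: SpectrumTable) -> SpectrumTable:
    """Standard normal variate: per row, subtract the mean and divide by the
    sample (n-1) standard deviation.  Constant rows are excluded."""
    if table.n_bands < 2:
        raise ConfigurationError("SNV needs at least 2 bands per spectrum")
    X = table.X
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    keep = (sd > 0).ravel()
    out = np.zeros_like(X)
    out[keep] = (X[keep] - mean[keep]) / sd[keep]
    dropped = [(table.sample_ids[i], "constant spectrum") for i in np.flatnonzero(~keep)]
    return _finish(table, out, keep, "snv", dropped)


def msc(
    table: SpectrumTable,
    reference: np.ndarray | None = None,
    *,
    slope_floor: float = 1e-8,
) -> SpectrumTable:
    """Multiplicative scatter correction against a reference spectrum.

    Each row ``x`` is modelled as ``x ~ a + b * reference`` by least squares
    and corrected to ``(x - a) / b``.  The reference defaults to the table's
    mean spectrum; pass the training-set reference explicitly when
    transforming held-out data.  Rows with ``|b|`` below ``slope_floor`` are
    excluded.
    """
    X = table.X
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != (table.n_bands,):
        raise ConfigurationError("MSC reference length must equal the band count")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0.0:
        raise ConfigurationError("MSC reference is constant")
    Xc = X - X.mean(axis=1, keepdims=True)
    b = (Xc @ ref_c) / denom
    a = X.mean(axis=1) - b * ref.mean()
    keep = np.abs(b) > slope_floor
    out = np.zeros_like(X)
    out[keep] = (X[keep] - a[keep, None]) / b[keep, None]
    dropped = [(table.sample_ids[i], "near-zero MSC slope") for i in np.flatnonzero(~keep)]
    res = _finish(table, out, keep, "msc", dropped)
    res.msc_reference = ref  # type: ignore[attr-defined]
    return res


def detrend(table: SpectrumTable, order: int = 2) -> SpectrumTable:
    """Subtract, per row, the least-squares polynomial of ``order`` in wavelength."""
    if order < 1:
        raise ConfigurationError("detrend order must be >= 1")
    if order >= table.n_bands - 1:
        raise ConfigurationError(
            f"detrend order {order} too high for {table.n_bands} bands"
        )
    # orthonormal polynomial basis in wavelength for numerical stability
    wl = table.wavelengths
    t = (wl - wl.mean()) / (np.ptp(wl) / 2 if np.ptp(wl) > 0 else 1.0)
    V = np.vander(t, order + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    X = table.X
    out = X - (X @ Q) @ Q.T
    return _finish(table, out, np.ones(table.n_samples, dtype=bool), "detrend", [])


def _upper_hull_envelope(wl: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Piecewise-linear upper convex hull of (wl, y), evaluated on wl.

    Andrew's monotone chain restricted to the upper hull; both endpoints are
    always hull vertices.
    """
    hull: list[int] = []
    for i in range(len(wl)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # pop i2 if it lies below the chord i1 -> i
            cross = (wl[i2] - wl[i1]) * (y[i] - y[i1]) - (y[i2] - y[i1]) * (wl[i] - wl[i1])
            if cross >= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(wl, wl[hull], y[hull])


def continuum_removal(table: SpectrumTable) -> SpectrumTable:
    """Divide each spectrum by its upper convex hull (continuum).

    Emphasizes absorption features: output values lie in (0, 1], with 1 at
    hull vertices (including both endpoints).  Rows with non-positive values
    are excluded.
    """
    if np.any(np.diff(table.wavelengths) <= 0):
        raise ConfigurationError("continuum removal needs strictly increasing wavelengths")
    X = table.X
    keep = (X > 0).all(axis=1)
    out = np.ones_like(X)
    wl = table.wavelengths
    for i in np.flatnonzero(keep):
        env = _upper_hull_envelope(wl, X[i])
        out[i] = X[i] / env
    dropped = [(table.sample_ids[i], "non-positive reflectance") for i in np.flatnonzero(~keep)]
    return _finish(table, out, keep, "continuum_removal", dropped)


def savgol_derivative(
    table: SpectrumTable,
    deriv: int = 1,
    window: int = 11,
    polyorder: int | None = None,
) -> SpectrumTable:
    """Savitzky–Golay derivative filtering, per row.

    ``polyorder`` defaults to 2 for the first derivative and 3 for the
    second.  Derivatives are taken with respect to the band index (unit
    spacing); edges are handled by fitting the edge polynomial on the
    one-sided window (``mode="interp"``).
    """
    if deriv not in (1, 2):
        raise ConfigurationError("deriv must be 1 or 2")
    if polyorder is None:
        polyorder = 2 if deriv == 1 else 3
    if window % 2 == 0 or window < 3:
        raise ConfigurationError("window must be an odd integer >= 3")
    if polyorder >= window:
        raise ConfigurationError("polyorder must be smaller than the window")
    if deriv > polyorder:
        raise ConfigurationError("deriv must not exceed polyorder")
    if window > table.n_bands:
        raise ConfigurationError("window exceeds the number of bands")
    out = savgol_filter(table.X, window, polyorder, deriv=deriv, axis=1, mode="interp")
    return _finish(table, out, np.ones(table.n_samples, dtype=bool), f"sg{deriv}", [])


def apply(spec: PreprocessSpec, table: SpectrumTable) -> SpectrumTable:
    """Dispatch a :class:`PreprocessSpec` to the named transform."""
    m = spec.method
    if m == "raw":
        out = table.with_values(table.X.copy(), step="raw")
        out.excluded = []  # type: ignore[attr-defined]
        return out
    if m == "snv":
        return snv(table)
    if m == "msc":
        return msc(table, **spec.params)
    if m == "detrend":
        return detrend(table, **spec.params)
    if m == "continuum_removal":
        return continuum_removal(table)
    if m == "sg1":
        return savgol_derivative(table, deriv=1, **spec.params)
    if m == "sg2":
        return savgol_derivative(table, deriv=2, **spec.params)
    raise ConfigurationError(f"unknown preprocessing method {m!r}")
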