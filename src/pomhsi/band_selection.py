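"""Informative-band selection via NWHFC virtual dimensionality and PCA loadings.

The number of spectrally distinct endmembers in a set of spectra is
estimated with the noise-whitened Harsanyi–Farrand–Chang (NWHFC) test:

1.  Per-band noise variances are estimated from the residuals of linearly
    regressing each band on all the others (equivalently, the reciprocal
    diagonal of the inverse covariance matrix), with a ridge fallback when
    the covariance is ill-conditioned.
2.  The data are whitened band-wise by the inverse noise standard
    deviations.
3.  The eigenvalues of the sample correlation matrix (non-centered second
    moment) and of the sample covariance matrix are sorted in decreasing
    order.  A signal direction contributes its mean to the correlation but
    not the covariance eigenvalue, so for each rank ``i`` the binary
    Neyman–Pearson test rejects noise when ``lambdaR_i - lambdaK_i``
    exceeds a threshold set by the false-alarm probability ``Pf`` under the
    asymptotic null variance ``(2/n) * (lambdaR_i^2 + lambdaK_i^2)``.
4.  The number of rejections is the endmember count ``k``.

That many informative bands are then picked from a PCA of the spectra: for
each of the first ``k`` components in order, the band with the largest
absolute loading is selected (collisions fall through to the next-largest
unclaimed band; ties break toward the lower band index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import ConfigurationError
from .spectra import SpectrumTable

__all__ = [
    "EndmemberEstimate",
    "BandSet",
    "estimate_endmembers_nwhfc",
    "select_bands",
    "reduce_table",
]


@dataclass
class EndmemberEstimate:
    """Result of the NWHFC test."""

    k: int
    corr_eigenvalues: np.ndarray  # sorted decreasing
    cov_eigenvalues: np.ndarray  # sorted decreasing
    thresholds: np.ndarray
    pf: float
    noise_std: np.ndarray
    ridge: float = 0.0  # jitter added to stabilize the noise estimate, if any

    def __post_init__(self) -> None:
        if self.k < 0 or self.k > len(self.corr_eigenvalues):
            raise ConfigurationError("endmember count out of range")


@dataclass
class BandSet:
    """Selected informative bands: 0-based indices plus wavelengths in nm."""

    indices: np.ndarray  # sorted ascending, unique
    wavelengths: np.ndarray  # nm, consistent with indices
    provenance: dict[int, int] = field(default_factory=dict)  # band index -> component
    k: int | None = None
    pf: float | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ConfigurationError("band indices must be unique")
        if np.any(np.diff(self.indices) <= 0):
            raise ConfigurationError("band indices must be sorted ascending")
        if len(self.indices) != len(self.wavelengths):
            raise ConfigurationError("indices and wavelengths must align")

    def to_dict(self) -> dict:
        return {
            "indices": self.indices.tolist(),
            "wavelengths_nm": self.wavelengths.tolist(),
            "k": self.k,
            "pf": self.pf,
            "provenance": {str(b): c for b, c in self.provenance.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandSet":
        return cls(
            np.asarray(d["indices"], dtype=int),
            np.asarray(d["wavelengths_nm"], dtype=float),
            {int(b): int(c) for b, c in d.get("provenance", {}).items()},
            d.get("k"),
            d.get("pf"),
        )


def _as_matrix(data: SpectrumTable | np.ndarray) -> np.ndarray:
    X = data.X if isinstance(data, SpectrumTable) else np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ConfigurationError("expected a 2-D (samples x bands) matrix")
    if not np.all(np.isfinite(X)):
        raise ConfigurationError("non-finite values in input spectra")
    return X


def estimate_noise_std(X: np.ndarray, *, ridge_scale: float = 1e-6) -> tuple[np.ndarray, float]:
    """Regression-residual estimate of per-band noise standard deviations.

    The residual variance of regressing band ``i`` on all other bands equals
    ``1 / (Sigma^{-1})_{ii}`` for the centered covariance ``Sigma``.  When
    ``Sigma`` is singular or ill-conditioned (fewer samples than bands), a
    ridge ``ridge_scale * mean(diag(Sigma))`` is added and reported.
    """
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    # population (1/n) normalization keeps the estimate an exact function of
    # the sample moments (e.g. invariant under duplicating every sample)
    sigma = (Xc.T @ Xc) / n
    ridge = 0.0
    eigmin = np.linalg.eigvalsh(sigma)[0]
    if eigmin <= 0 or np.linalg.cond(sigma) > 1e12:
        ridge = ridge_scale * float(np.trace(sigma)) / p
        sigma = sigma + ridge * np.eye(p)
    inv = np.linalg.inv(sigma)
    noise_var = 1.0 / np.clip(np.diag(inv), 1e-300, None)
    return np.sqrt(noise_var), ridge


def estimate_endmembers_nwhfc(
    data: SpectrumTable | np.ndarray,
    pf: float = 1e-3,
    *,
    whiten: bool = True,
) -> EndmemberEstimate:
    """NWHFC estimate of the number of spectrally distinct endmembers.

    ``data`` is an (n_samples x n_bands) matrix of spectra (pixel spectra or
    ROI means).  ``pf`` is the per-rank false-alarm probability of the
    Neyman–Pearson eigenvalue test.  Set ``whiten=False`` for the plain HFC
    variant.
    """
    if not 0.0 < pf < 0.5:
        raise ConfigurationError(f"Pf must lie in (0, 0.5), got {pf}")
    X = _as_matrix(data)
    n, p = X.shape
    if n < 2:
        raise ConfigurationError("need at least 2 samples")

    ridge = 0.0
    if whiten:
        noise_std, ridge = estimate_noise_std(X)
        Xw = X / noise_std
    else:
        noise_std = np.ones(p)
        Xw = X

    corr = (Xw.T @ Xw) / n  # non-centered second moment
    Xc = Xw - Xw.mean(axis=0)
    cov = (Xc.T @ Xc) / n  # covariance with matching 1/n normalization

    lam_r = np.sort(np.linalg.eigvalsh(corr))[::-1]
    lam_k = np.sort(np.linalg.eigvalsh(cov))[::-1]

    z = stats.norm.isf(pf)
    null_sd = np.sqrt((2.0 / n) * (lam_r**2 + lam_k**2))
    thresholds = z * null_sd
    rejected = (lam_r - lam_k) > thresholds
    k = int(np.count_nonzero(rejected))
    return EndmemberEstimate(k, lam_r, lam_k, thresholds, pf, noise_std, ridge)


def pca_loadings(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Loadings (bands x components) and variances of a mean-centered PCA.

    Deterministic sign convention: each loading vector is flipped so its
    largest-magnitude entry is positive.
    """
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / max(X.shape[0] - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] *= -1
    return vecs, vals


def select_bands(table: SpectrumTable, k: int, *, pf: float | None = None) -> BandSet:
    """Pick ``k`` informative bands from PCA loadings of a spectrum table.

    For each of the first ``k`` principal components in order, the band with
    the largest absolute loading is claimed; if it is already claimed by an
    earlier component, the next-largest unclaimed band for that component is
    taken instead.  Ties break toward the lower band index.
    """
    p = table.n_bands
    if not 1 <= k <= p:
        raise ConfigurationError(f"k must lie in [1, {p}], got {k}")
    loadings, _ = pca_loadings(table.X)
    claimed: dict[int, int] = {}  # band -> component
    for comp in range(k):
        weights = np.abs(loadings[:, comp])
        # stable descending order; ties resolve to the lower band index
        order = np.argsort(-weights, kind="stable")
        chosen = next((int(b) for b in order if int(b) not in claimed), None)
        if chosen is None:
            raise ConfigurationError(f"no unclaimed band left for component {comp}")
        claimed[chosen] = comp
    idx = np.array(sorted(claimed), dtype=int)
    return BandSet(
        idx,
        table.wavelengths[idx],
        provenance={b: claimed[b] for b in idx.tolist()},
        k=k,
        pf=pf,
    )


def reduce_table(table: SpectrumTable, bands: BandSet) -> SpectrumTable:
    """Restrict a spectrum table to the selected bands (ascending wavelength)."""
    if bands.indices.size and bands.indices.max() >= table.n_bands:
        raise ConfigurationError("band index out of range for this table")
    if not np.allclose(table.wavelengths[bands.indices], bands.wavelengths):
        raise ConfigurationError("band set wavelengths do not match the table grid")
    return table.take_bands(bands.indices, step=f"reduce[{len(bands.indices)}]")
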