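"""PCA-based background removal and ROI spectrum extraction.

The fruit is isolated from the (spectrally distinct) background by scoring
every pixel on the first principal component of the pixel-spectra cloud,
thresholding the score image with Otsu's method, keeping the largest
connected component on the fruit side and filling its holes.  The fruit
side of the threshold is chosen automatically as the spatially compact
class — in practice the class with the smaller fraction of pixels on the
image border, since the background always reaches the frame edge in a
line-scan acquisition.

The sample's feature vector is then the arithmetic mean spectrum over the
region of interest (by default the whole fruit face; a ground-truth bruise
mask can be substituted when working with synthetic scenes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from sklearn.decomposition import PCA

from .core import ConfigurationError, HyperCube, ShapeError
from .spectra import SpectrumTable

__all__ = [
    "PixelPCA",
    "SegmentationError",
    "pixel_pca",
    "pooled_pixel_pca",
    "background_mask",
    "segment_cube",
    "roi_mean_spectrum",
    "build_spectrum_table",
]


class SegmentationError(RuntimeError):
    """No usable fruit region could be isolated."""


@dataclass
class PixelPCA:
    """Per-pixel PCA of a reflectance cube.

    ``scores`` has shape (lines, samples, n_components); ``loadings`` has
    shape (n_bands, n_components) with orthonormal columns; explained
    variances are non-increasing.  ``degenerate`` flags a cube whose pixels
    are all identical (scores are all zero in that case).
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    mean: np.ndarray
    degenerate: bool = False


def pixel_pca(cube: HyperCube, n_components: int = 3) -> PixelPCA:
    """PCA of the pixel-spectra matrix (pixels as observations, bands as variables).

    Pixels are flattened to an ``(n_pixels, n_bands)`` matrix and
    mean-centered over pixels.  Variances use the 1/(n-1) convention.
    """
    if cube.kind != "reflectance":
        raise ConfigurationError("pixel_pca expects a reflectance cube")
    h, w, p = cube.shape
    if n_components > p:
        raise ConfigurationError(f"n_components ({n_components}) exceeds band count ({p})")
    X = cube.values.reshape(h * w, p).astype(np.float64)
    mean = X.mean(axis=0)
    if np.allclose(X, mean, atol=1e-12):
        return PixelPCA(
            scores=np.zeros((h, w, n_components)),
            loadings=np.eye(p)[:, :n_components],
            explained_variance=np.zeros(n_components),
            mean=mean,
            degenerate=True,
        )
    pca = PCA(n_components=n_components, svd_solver="auto", random_state=0)
    flat_scores = pca.fit_transform(X)
    return PixelPCA(
        scores=flat_scores.reshape(h, w, n_components),
        loadings=pca.components_.T,
        explained_variance=pca.explained_variance_,
        mean=mean,
        degenerate=False,
    )


def pooled_pixel_pca(cubes: list[HyperCube], n_components: int = 3) -> PixelPCA:
    """PCA of the pooled pixel spectra of several cubes (group mode).

    All cubes must share one wavelength grid; scores are returned stacked
    along the scan axis in input order.  The per-cube mode
    (:func:`pixel_pca`) is the default throughout the pipeline.
    """
    if not cubes:
        raise ConfigurationError("pooled_pixel_pca needs at least one cube")
    first = cubes[0]
    for cube in cubes[1:]:
        if not first.same_grid(cube):
            raise ShapeError("pooled cubes must share one wavelength grid")
        if cube.shape[1] != first.shape[1]:
            raise ShapeError("pooled cubes must share the spatial line width")
    stacked = HyperCube(
        np.concatenate([c.values for c in cubes], axis=0),
        first.wavelengths.copy(),
        "reflectance",
        {"pooled": len(cubes)},
    )
    return pixel_pca(stacked, n_components)


def _border_fraction(mask: np.ndarray) -> float:
    total = mask.sum()
    if total == 0:
        return np.inf
    border = (
        mask[0, :].sum() + mask[-1, :].sum() + mask[1:-1, 0].sum() + mask[1:-1, -1].sum()
    )
    return border / total


def background_mask(score_image: np.ndarray) -> np.ndarray:
    """Segment the fruit from a first-PC score image.

    Otsu's threshold splits pixels in two classes; the fruit side is the
    spatially compact one (smaller border-pixel fraction, the background
    always touching the frame edge).  Only the largest connected component
    is kept and its holes are filled.

    Returns the boolean fruit mask; raises :class:`SegmentationError` when
    no fruit-side pixels survive.
    """
    score = np.asarray(score_image, dtype=float)
    if score.ndim != 2:
        raise ShapeError("score image must be 2-D")
    finite = np.isfinite(score)
    if not finite.any() or np.ptp(score[finite]) == 0:
        raise SegmentationError("score image is constant; nothing to segment")
    thr = threshold_otsu(score[finite])
    above = score > thr
    below = ~above & finite
    if not above.any() or not below.any():
        raise SegmentationError("Otsu threshold produced a single class")

    # the fruit class is the spatially compact one
    fruit_side = above if _border_fraction(above) <= _border_fraction(below) else below

    labels, n = cc_label(fruit_side, return_num=True, connectivity=2)
    if n == 0:
        raise SegmentationError("no connected component on the fruit side")
    sizes = np.bincount(labels.ravel())[1:]
    largest = int(np.argmax(sizes)) + 1
    mask = labels == largest
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise SegmentationError("empty fruit mask after post-processing")
    return mask


def segment_cube(cube: HyperCube) -> np.ndarray:
    """Convenience: PC-1 scores then :func:`background_mask`."""
    res = pixel_pca(cube, n_components=1)
    if res.degenerate:
        raise SegmentationError("constant cube; nothing to segment")
    return background_mask(res.scores[:, :, 0])


def roi_mean_spectrum(cube: HyperCube, mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean spectrum over the masked pixels, per band.

    Pixels flagged invalid by calibration (``metadata["invalid_mask"]``) are
    excluded from the average.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ShapeError("mask shape does not match cube spatial dimensions")
    invalid = cube.metadata.get("invalid_mask")
    effective = mask & ~invalid if invalid is not None else mask
    n = int(effective.sum())
    if n == 0:
        raise SegmentationError("ROI mask is empty (after excluding invalid pixels)")
    return cube.values[effective].mean(axis=0).astype(float)


def build_spectrum_table(
    cubes: list[HyperCube],
    masks: list[np.ndarray],
    labels: list[str],
    sample_ids: list[str] | None = None,
) -> SpectrumTable:
    """Assemble one ROI-averaged spectrum per sample into a labelled table.

    Per-sample failures (empty masks, shape mismatches) are collected on the
    returned table's ``failures`` attribute as ``(sample_id, message)`` pairs
    and the offending rows are excluded rather than aborting the batch.
    """
    if not (len(cubes) == len(masks) == len(labels)):
        raise ShapeError("cubes, masks and labels must have equal lengths")
    if sample_ids is None:
        sample_ids = [f"s{i:03d}" for i in range(len(cubes))]
    rows, kept_labels, kept_ids = [], [], []
    failures: list[tuple[str, str]] = []
    wavelengths = cubes[0].wavelengths if cubes else np.array([])
    for cube, mask, lab, sid in zip(cubes, masks, labels, sample_ids):
        try:
            if len(rows) and not np.allclose(cube.wavelengths, wavelengths):
                raise ShapeError("wavelength grid differs from the first sample")
            rows.append(roi_mean_spectrum(cube, mask))
            kept_labels.append(lab)
            kept_ids.append(sid)
        except (SegmentationError, ShapeError) as exc:
            failures.append((sid, str(exc)))
    X = np.vstack(rows) if rows else np.empty((0, len(wavelengths)))
    table = SpectrumTable(X, wavelengths, kept_labels, kept_ids, history=["roi_mean"])
    table.failures = failures  # type: ignore[attr-defined]
    return table
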