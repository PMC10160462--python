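"""Synthetic hyperspectral scene generator for fruit-bruise studies.

Emulates a line-scan acquisition of a fruit resting on a dark background:
a true-reflectance cube is built as a per-pixel linear mixture of three
endmember spectra (background, sound fruit rind, bruised rind), modulated by
a smooth illumination field, offset by dark current, perturbed by Gaussian
sensor noise, and digitized to integer counts.  A matching white-reference
frame (grey calibration panel of known reflectivity under the same
illumination) and a dark frame are rendered alongside, so the white/dark
correction is exercised end-to-end exactly as it would be on real frames.

Bruise severity classes follow the drop-test design of impact-bruise
studies: ``no_drop`` (sound fruit), ``drop_60`` and ``drop_100`` (bruising
induced by 60 cm and 100 cm drops).  Bruising expresses spectrally as a
*reduction of reflectance* concentrated around the water absorption bands
(~1450 and ~1940 nm in the SWIR; ~970 nm in the VNIR) — bruised tissue leaks
water toward the surface, deepening those features — scaled so the band-mean
reflectance drops by a configurable amount per severity.  This reproduces
the empirical ordering sound > 60 cm > 100 cm of class-mean SWIR spectra
while changing spectral *shape*, not just offset, so scatter-correcting
preprocessing does not erase the class signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import CameraProfile, ConfigurationError, HyperCube

__all__ = [
    "SEVERITY_CLASSES",
    "SEVERITY_SHIFTS",
    "EndmemberSet",
    "SceneConfig",
    "FrameTriplet",
    "SceneSample",
    "LabeledDataset",
    "generate_endmembers",
    "render_scene",
    "iter_dataset",
    "generate_dataset",
    "expected_fruit_roi_spectrum",
]

#: Severity classes in increasing bruise severity order.
SEVERITY_CLASSES = ("no_drop", "drop_60", "drop_100")

#: Default band-mean reflectance reduction of the bruised endmember relative
#: to sound rind, per severity class (reflectance units).
SEVERITY_SHIFTS = {"no_drop": 0.0, "drop_60": 0.06, "drop_100": 0.10}

#: Water absorption band centres (nm) used to localize the bruise signature.
WATER_BANDS_NM = (970.0, 1450.0, 1940.0)


@dataclass
class EndmemberSet:
    """Background / fruit / bruise reflectance curves on one wavelength grid."""

    wavelengths: np.ndarray
    background: np.ndarray
    fruit: np.ndarray
    bruise: np.ndarray
    severity: str = "no_drop"

    def __post_init__(self) -> None:
        for curve in (self.background, self.fruit, self.bruise):
            if curve.shape != self.wavelengths.shape:
                raise ConfigurationError("endmember curve does not match wavelength grid")
            if curve.min() < -1e-12 or curve.max() > 1 + 1e-12:
                raise ConfigurationError("endmember reflectance must lie in [0, 1]")


@dataclass
class SceneConfig:
    """Geometry, optics and sensor parameters for one rendered scene.

    Lengths are in pixels, reflectance quantities dimensionless, counts in
    digitizer units.  ``noise_sd`` is the per-pixel Gaussian noise standard
    deviation expressed in reflectance units (it is scaled by gain and
    illumination before digitization).  Reference frames are modelled as
    ``reference_averages``-fold averages, so their noise is reduced by the
    square root of that factor.
    """

    height: int = 128
    width: int = 128
    fruit_center: tuple[float, float] = (64.0, 64.0)  # (row, col)
    fruit_radius: float = 42.0
    bruise_center: tuple[float, float] | None = None
    bruise_axes: tuple[float, float] = (18.0, 14.0)
    mixing_fraction: float = 0.85
    severity: str = "no_drop"
    illumination_amplitude: float = 0.10
    noise_sd: float = 0.02
    dark_offset: float = 500.0
    gain: float = 30000.0
    rho_ref: float = 0.5
    reference_averages: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.severity not in SEVERITY_CLASSES:
            raise ConfigurationError(f"unknown severity {self.severity!r}")
        if not 0.0 <= self.mixing_fraction <= 1.0:
            raise ConfigurationError("mixing_fraction must be in [0, 1]")
        if self.severity == "no_drop" and self.bruise_center is not None:
            raise ConfigurationError("no_drop scenes must not carry a bruise region")
        if self.severity != "no_drop":
            if self.bruise_center is None:
                self.bruise_center = self.fruit_center
            # the bruise ellipse must sit inside the fruit disc
            dr = self.bruise_center[0] - self.fruit_center[0]
            dc = self.bruise_center[1] - self.fruit_center[1]
            reach = np.hypot(dr, dc) + max(self.bruise_axes)
            if reach > self.fruit_radius:
                raise ConfigurationError("bruise ellipse extends outside the fruit disc")


@dataclass
class FrameTriplet:
    """Raw scene frame plus white-reference and dark frames, all in counts."""

    raw: HyperCube
    white: HyperCube
    dark: HyperCube
    rho_ref: float

    def __post_init__(self) -> None:
        if not (self.raw.same_grid(self.white) and self.raw.same_grid(self.dark)):
            raise ConfigurationError("frame triplet must share one wavelength grid")
        if self.raw.shape != self.white.shape or self.raw.shape != self.dark.shape:
            raise ConfigurationError("frame triplet must share dimensions")


@dataclass
class SceneSample:
    """One labelled scene: frames, ground truth and generating config."""

    sample_id: str
    label: str
    frames: FrameTriplet
    config: SceneConfig
    fruit_mask: np.ndarray
    bruise_mask: np.ndarray
    true_reflectance: HyperCube
    endmembers: EndmemberSet


@dataclass
class LabeledDataset:
    """A list of labelled scenes with the profile that produced them."""

    samples: list[SceneSample]
    profile: CameraProfile
    seed: int

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.samples]


def _gaussian(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _bruise_dip_basis(wavelengths: np.ndarray, width_nm: float = 120.0) -> np.ndarray:
    """Unit-mean absorption profile localizing the bruise signature.

    Gaussian dips are placed at the water absorption bands falling inside the
    grid; if none falls inside (an unusual custom range), two dips at 1/3 and
    2/3 of the range are used so the basis is never empty.
    """
    lo, hi = wavelengths[0], wavelengths[-1]
    centers = [c for c in WATER_BANDS_NM if lo <= c <= hi]
    if not centers:
        centers = [lo + (hi - lo) / 3.0, lo + 2.0 * (hi - lo) / 3.0]
    basis = np.zeros_like(wavelengths)
    for c in centers:
        basis += _gaussian(wavelengths, c, width_nm)
    return basis / basis.mean()


# Fixed fruit-rind bump layout in normalized wavelength coordinates: a broad
# reflectance plateau with gentle undulations, qualitatively matching smooth
# rind reflectance curves.
_FRUIT_BUMPS = (
    # (center, width, amplitude) in normalized [0, 1] wavelength units
    (0.12, 0.16, 0.22),
    (0.38, 0.20, 0.16),
    (0.62, 0.16, 0.20),
    (0.88, 0.18, 0.14),
)
_FRUIT_BASE = 0.16
_BACKGROUND_BASE = 0.05


def generate_endmembers(
    profile: CameraProfile,
    severity: str = "no_drop",
    seed: int = 0,
    *,
    severity_shift: float | None = None,
    amplitude_jitter: float = 0.02,
    level_jitter: float = 0.03,
    dip_width_nm: float = 120.0,
) -> EndmemberSet:
    """Build background, fruit and bruise reflectance curves for one scene.

    The fruit curve is a fixed sum of Gaussian bumps with per-bump amplitude
    jitter and a global level jitter (sample-to-sample biological variation).
    The bruise curve subtracts a water-band absorption profile scaled so the
    band-mean reflectance drops by ``severity_shift`` (defaults per class:
    0, 0.06, 0.10 for no_drop / drop_60 / drop_100).  For ``no_drop`` the
    bruise curve equals the fruit curve.  Deterministic for a fixed seed.
    """
    if severity not in SEVERITY_CLASSES:
        raise ConfigurationError(f"unknown severity {severity!r}")
    rng = np.random.default_rng(seed)
    wl = profile.wavelengths
    t = (wl - wl[0]) / (wl[-1] - wl[0])

    level = 1.0 + level_jitter * rng.standard_normal()
    fruit = np.full_like(t, _FRUIT_BASE)
    for center, width, amp in _FRUIT_BUMPS:
        amp_j = amp * (1.0 + amplitude_jitter * rng.standard_normal())
        fruit += amp_j * _gaussian(t, center, width)
    fruit = np.clip(fruit * level, 0.0, 1.0)

    bg_level = 1.0 + 0.05 * rng.standard_normal()
    background = np.clip((_BACKGROUND_BASE + 0.03 * t) * bg_level, 0.0, 1.0)

    shift = SEVERITY_SHIFTS[severity] if severity_shift is None else severity_shift
    if severity == "no_drop" or shift == 0.0:
        bruise = fruit.copy()
    else:
        dip = _bruise_dip_basis(wl, dip_width_nm)
        bruise = np.clip(fruit - shift * dip, 0.0, 1.0)
    return EndmemberSet(wl, background, fruit, bruise, severity)


def _disc_mask(h: int, w: int, center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[:h, :w]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ellipse_mask(
    h: int, w: int, center: tuple[float, float], axes: tuple[float, float]
) -> np.ndarray:
    rr, cc = np.ogrid[:h, :w]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _illumination_field(h: int, w: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative illumination: tilted plane plus a broad lobe."""
    if amplitude == 0.0:
        return np.ones((h, w))
    rr, cc = np.meshgrid(np.linspace(-1, 1, h), np.linspace(-1, 1, w), indexing="ij")
    tilt_dir = rng.uniform(0, 2 * np.pi)
    lobe_r = rng.uniform(-0.5, 0.5)
    lobe_c = rng.uniform(-0.5, 0.5)
    tilt = np.cos(tilt_dir) * rr + np.sin(tilt_dir) * cc
    lobe = np.exp(-((rr - lobe_r) ** 2 + (cc - lobe_c) ** 2) / 0.8)
    field = 1.0 + amplitude * (0.5 * tilt + 0.5 * (lobe - lobe.mean()))
    return np.clip(field, 0.05, None)


def render_scene(
    config: SceneConfig,
    endmembers: EndmemberSet,
    profile: CameraProfile,
) -> SceneSample:
    """Render one scene into raw / white / dark count frames plus ground truth.

    The true-reflectance cube mixes background, fruit and bruise endmembers
    per pixel (``mixing_fraction`` of bruise inside the bruise ellipse), is
    multiplied by a smooth illumination field and the digitizer gain, offset
    by dark current, perturbed by Gaussian noise and rounded to integer
    counts clipped to the bit depth.  Counts that hit the clip limits are
    tallied in ``raw.metadata["n_clipped"]``.
    """
    if not np.allclose(endmembers.wavelengths, profile.wavelengths):
        raise ConfigurationError("endmembers were built on a different wavelength grid")
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    wl = profile.wavelengths

    fruit_mask = _disc_mask(h, w, config.fruit_center, config.fruit_radius)
    if config.severity != "no_drop":
        bruise_mask = _ellipse_mask(h, w, config.bruise_center, config.bruise_axes)
        bruise_mask &= fruit_mask
    else:
        bruise_mask = np.zeros((h, w), dtype=bool)

    # per-pixel linear mixture of the three endmembers
    true_cube = np.empty((h, w, profile.n_bands), dtype=np.float32)
    true_cube[:] = endmembers.background.astype(np.float32)
    true_cube[fruit_mask] = endmembers.fruit.astype(np.float32)
    m = config.mixing_fraction
    mixed = ((1.0 - m) * endmembers.fruit + m * endmembers.bruise).astype(np.float32)
    true_cube[bruise_mask] = mixed

    illum = _illumination_field(h, w, config.illumination_amplitude, rng).astype(np.float32)
    scale = (config.gain * illum)[:, :, None]

    def digitize(analog: np.ndarray, meta: dict) -> np.ndarray:
        counts = np.rint(analog)
        n_clipped = int(np.count_nonzero(counts < 0) + np.count_nonzero(counts > profile.max_count))
        meta["n_clipped"] = n_clipped
        return np.clip(counts, 0, profile.max_count).astype(np.uint16)

    raw_meta: dict = {"profile": profile.name, "seed": config.seed, "severity": config.severity}
    white_meta: dict = {"profile": profile.name, "role": "white"}
    dark_meta: dict = {"profile": profile.name, "role": "dark"}

    noise = np.float32(config.noise_sd) * rng.standard_normal(true_cube.shape, dtype=np.float32)
    raw_analog = scale * (true_cube + noise) + np.float32(config.dark_offset)

    ref_sd = config.noise_sd / np.sqrt(max(config.reference_averages, 1))
    white_noise = np.float32(ref_sd) * rng.standard_normal(true_cube.shape, dtype=np.float32)
    white_analog = scale * (np.float32(config.rho_ref) + white_noise) + np.float32(config.dark_offset)

    # dark current is modelled as a uniform noise-free offset
    dark_analog = np.full_like(raw_analog, config.dark_offset)

    raw = HyperCube(digitize(raw_analog, raw_meta), wl, "counts", raw_meta)
    white = HyperCube(digitize(white_analog, white_meta), wl, "counts", white_meta)
    dark = HyperCube(digitize(dark_analog, dark_meta), wl, "counts", dark_meta)

    true = HyperCube(
        true_cube, wl, "reflectance", {"profile": profile.name, "ground_truth": True}
    )
    return SceneSample(
        sample_id=f"{profile.name}_{config.severity}_{config.seed}",
        label=config.severity,
        frames=FrameTriplet(raw, white, dark, config.rho_ref),
        config=config,
        fruit_mask=fruit_mask,
        bruise_mask=bruise_mask,
        true_reflectance=true,
        endmembers=endmembers,
    )


def expected_fruit_roi_spectrum(sample: SceneSample) -> np.ndarray:
    """Analytic expectation of the mean spectrum over the ground-truth fruit mask."""
    n_fruit = int(sample.fruit_mask.sum())
    n_bruise = int(sample.bruise_mask.sum())
    m = sample.config.mixing_fraction
    em = sample.endmembers
    mixed = (1.0 - m) * em.fruit + m * em.bruise
    return ((n_fruit - n_bruise) * em.fruit + n_bruise * mixed) / n_fruit


def iter_dataset(
    n_per_class: int,
    profile: CameraProfile,
    seed: int = 0,
    *,
    severity_shifts: dict[str, float] | None = None,
    noise_sd: float = 0.02,
    height: int = 128,
    width: int = 128,
    classes: Sequence[str] = SEVERITY_CLASSES,
    mixing_fraction: float = 0.85,
):
    """Yield ``n_per_class`` labelled scenes per severity class, one at a time.

    Per-scene seeds are derived from the master seed via a seed sequence, and
    per-scene geometry (fruit radius and position, bruise ellipse, lighting)
    is jittered so samples within a class are not identical.  Streaming keeps
    only one frame triplet in memory, which matters for full-size datasets.
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    shifts = dict(SEVERITY_SHIFTS)
    if severity_shifts:
        shifts.update(severity_shifts)

    master = np.random.default_rng(np.random.SeedSequence(seed))
    idx = 0
    for cls in classes:
        for _ in range(n_per_class):
            scene_seed = int(master.integers(0, 2**31 - 1))
            jit = np.random.default_rng(scene_seed)
            radius = jit.uniform(0.28, 0.36) * min(height, width)
            center = (
                height / 2 + jit.uniform(-4, 4),
                width / 2 + jit.uniform(-4, 4),
            )
            if cls == "no_drop":
                bruise_center = None
                axes = (1.0, 1.0)
            else:
                ax_a = jit.uniform(0.35, 0.5) * radius
                ax_b = jit.uniform(0.3, 0.42) * radius
                axes = (ax_a, ax_b)
                max_off = max(radius - max(axes) - 1.0, 0.0)
                ang = jit.uniform(0, 2 * np.pi)
                off = jit.uniform(0, 0.5 * max_off)
                bruise_center = (center[0] + off * np.sin(ang), center[1] + off * np.cos(ang))
            config = SceneConfig(
                height=height,
                width=width,
                fruit_center=center,
                fruit_radius=radius,
                bruise_center=bruise_center,
                bruise_axes=axes,
                mixing_fraction=mixing_fraction if cls != "no_drop" else 0.0,
                severity=cls,
                illumination_amplitude=jit.uniform(0.05, 0.15),
                noise_sd=noise_sd,
                seed=scene_seed,
            )
            em = generate_endmembers(
                profile, cls, seed=scene_seed + 1, severity_shift=shifts[cls]
            )
            sample = render_scene(config, em, profile)
            sample.sample_id = f"s{idx:03d}_{cls}"
            yield sample
            idx += 1


def generate_dataset(
    n_per_class: int,
    profile: CameraProfile,
    seed: int = 0,
    **kwargs,
) -> LabeledDataset:
    """Materialize :func:`iter_dataset` into a :class:`LabeledDataset`.

    Convenient for small scenes; for full-size datasets prefer streaming
    with :func:`iter_dataset` and processing each sample as it is produced.
    """
    samples = list(iter_dataset(n_per_class, profile, seed, **kwargs))
    return LabeledDataset(samples, profile, seed)
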