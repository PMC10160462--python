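import numpy as np
import pytest

from pomhsi.calibration import calibrate
from pomhsi.core import ConfigurationError
from pomhsi.synthetic import (
    SEVERITY_CLASSES,
    SceneConfig,
    expected_fruit_roi_spectrum,
    generate_dataset,
    generate_endmembers,
    iter_dataset,
    render_scene,
)


class TestEndmembers:
    def test_no_drop_bruise_equals_fruit(self, swir):
        em = generate_endmembers(swir, "no_drop", seed=5)
        assert np.array_equal(em.bruise, em.fruit)

    def test_severity_ordering_of_band_means(self, swir):
        """Sound rind reflects most; deeper bruises reflect less, on average."""
        em60 = generate_endmembers(swir, "drop_60", seed=5)
        em100 = generate_endmembers(swir, "drop_100", seed=5)
        assert em60.fruit.mean() > em60.bruise.mean() > em100.bruise.mean()

    def test_deterministic_for_fixed_seed(self, swir):
        a = generate_endmembers(swir, "drop_60", seed=11)
        b = generate_endmembers(swir, "drop_60", seed=11)
        assert np.array_equal(a.fruit, b.fruit)
        assert np.array_equal(a.bruise, b.bruise)
        assert np.array_equal(a.background, b.background)

    def test_curves_bounded_and_smooth(self, swir, vnir):
        for prof in (swir, vnir):
            em = generate_endmembers(prof, "drop_100", seed=2)
            for curve in (em.background, em.fruit, em.bruise):
                assert curve.min() >= 0.0 and curve.max() <= 1.0
                # smoothness: bounded first difference on the nm grid
                step = np.diff(prof.wavelengths).max()
                assert np.abs(np.diff(curve)).max() < 0.02 * step

    def test_unknown_severity_rejected(self, swir):
        with pytest.raises(ConfigurationError):
            generate_endmembers(swir, "drop_200", seed=0)


class TestSceneConfig:
    def test_bruise_must_fit_inside_fruit(self):
        with pytest.raises(ConfigurationError):
            SceneConfig(
                severity="drop_60",
                fruit_radius=20.0,
                bruise_center=(64.0, 80.0),
                bruise_axes=(10.0, 8.0),
            )

    def test_no_drop_cannot_carry_bruise(self):
        with pytest.raises(ConfigurationError):
            SceneConfig(severity="no_drop", bruise_center=(64.0, 64.0))


class TestRenderScene:
    def test_identity_sensor_counts_equal_scaled_reflectance(self, tiny_profile):
        """With no noise, flat lighting, unit panel: counts = gain * truth."""
        cfg = SceneConfig(
            height=24, width=24, fruit_center=(12, 12), fruit_radius=8,
            severity="no_drop", illumination_amplitude=0.0, noise_sd=0.0,
            dark_offset=0.0, gain=1000.0, rho_ref=1.0, seed=3,
        )
        em = generate_endmembers(tiny_profile, "no_drop", seed=3)
        s = render_scene(cfg, em, tiny_profile)
        expected = np.rint(1000.0 * s.true_reflectance.values)
        assert np.array_equal(s.frames.raw.values.astype(float), expected)

    def test_zero_mixing_matches_no_bruise_render(self, tiny_profile):
        base = dict(height=24, width=24, fruit_center=(12, 12), fruit_radius=9, seed=17)
        em = generate_endmembers(tiny_profile, "drop_100", seed=17)
        bruised = SceneConfig(
            severity="drop_100", bruise_center=(12, 12), bruise_axes=(4, 3),
            mixing_fraction=0.0, **base,
        )
        em_sound = generate_endmembers(tiny_profile, "no_drop", seed=17)
        em_sound.fruit = em.fruit.copy()
        em_sound.bruise = em.fruit.copy()
        em_sound.background = em.background.copy()
        sound = SceneConfig(severity="no_drop", **base)
        s_b = render_scene(bruised, em, tiny_profile)
        s_s = render_scene(sound, em_sound, tiny_profile)
        assert np.array_equal(s_b.frames.raw.values, s_s.frames.raw.values)

    def test_white_exceeds_dark_at_every_band(self, tiny_profile):
        cfg = SceneConfig(height=32, width=32, fruit_center=(16, 16), fruit_radius=10,
                          severity="no_drop", seed=9)
        s = render_scene(cfg, generate_endmembers(tiny_profile, "no_drop", 9), tiny_profile)
        white_mean = s.frames.white.values.astype(float).mean(axis=(0, 1))
        dark_mean = s.frames.dark.values.astype(float).mean(axis=(0, 1))
        assert np.all(white_mean > dark_mean)

    def test_true_reflectance_within_unit_interval(self, tiny_profile):
        cfg = SceneConfig(height=32, width=32, fruit_center=(16, 16), fruit_radius=10,
                          severity="drop_100", bruise_axes=(4, 3), seed=9)
        s = render_scene(cfg, generate_endmembers(tiny_profile, "drop_100", 9), tiny_profile)
        vals = s.true_reflectance.values
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_noiseless_calibration_roundtrip_is_exact(self, tiny_profile):
        """White/dark correction undoes gain, lighting and dark offset up to
        the digitization quantum."""
        cfg = SceneConfig(height=32, width=32, fruit_center=(16, 16), fruit_radius=10,
                          severity="drop_60", bruise_axes=(4, 3),
                          noise_sd=0.0, seed=21)
        s = render_scene(cfg, generate_endmembers(tiny_profile, "drop_60", 21), tiny_profile)
        cube = calibrate(s.frames.raw, s.frames.white, s.frames.dark, s.frames.rho_ref)
        # quantization: |rho_err| <= rho_ref * (0.5 + 0.5|rho/rho_ref|) / (white - dark)
        denom = s.frames.white.values.astype(float) - s.frames.dark.values.astype(float)
        quantum = 1.0 / np.maximum(denom, 1.0)
        err = np.abs(cube.values - s.true_reflectance.values)
        assert np.all(err <= quantum + 1e-6)

    def test_noisy_calibration_recovers_truth_within_3_sigma(self, tiny_profile):
        cfg = SceneConfig(height=32, width=32, fruit_center=(16, 16), fruit_radius=10,
                          severity="drop_60", bruise_axes=(4, 3),
                          noise_sd=0.02, seed=22)
        s = render_scene(cfg, generate_endmembers(tiny_profile, "drop_60", 22), tiny_profile)
        cube = calibrate(s.frames.raw, s.frames.white, s.frames.dark, s.frames.rho_ref)
        err = np.abs(cube.values.astype(float) - s.true_reflectance.values)
        within = (err <= 3 * cfg.noise_sd).mean()
        assert within >= 0.99  # 3-sigma bound holds for ~99.7% of pixel-bands

    def test_overflow_counts_are_clipped_and_tallied(self, tiny_profile):
        cfg = SceneConfig(height=16, width=16, fruit_center=(8, 8), fruit_radius=5,
                          severity="no_drop", noise_sd=0.0, gain=1e6, seed=4)
        s = render_scene(cfg, generate_endmembers(tiny_profile, "no_drop", 4), tiny_profile)
        assert s.frames.raw.metadata["n_clipped"] > 0
        assert s.frames.raw.values.max() == tiny_profile.max_count


class TestGenerateDataset:
    def test_class_counts(self, tiny_profile):
        ds = generate_dataset(3, tiny_profile, seed=0, height=24, width=24)
        assert len(ds) == 9
        for cls in SEVERITY_CLASSES:
            assert sum(1 for s in ds if s.label == cls) == 3

    def test_bitwise_determinism(self, tiny_profile):
        a = generate_dataset(1, tiny_profile, seed=5, height=24, width=24)
        b = generate_dataset(1, tiny_profile, seed=5, height=24, width=24)
        for sa, sb in zip(a, b):
            assert sa.sample_id == sb.sample_id
            assert np.array_equal(sa.frames.raw.values, sb.frames.raw.values)
            assert np.array_equal(sa.fruit_mask, sb.fruit_mask)

    def test_masks_consistent(self, tiny_profile):
        for s in iter_dataset(2, tiny_profile, seed=1, height=32, width=32):
            assert s.bruise_mask.dtype == bool and s.fruit_mask.dtype == bool
            assert not np.any(s.bruise_mask & ~s.fruit_mask)  # bruise within fruit
            if s.label == "no_drop":
                assert not s.bruise_mask.any()
            else:
                assert s.bruise_mask.any()

    def test_roi_class_means_preserve_severity_ordering(self, swir):
        """Ground-truth-masked ROI means reproduce the class ordering
        sound > 60 cm > 100 cm in band-mean reflectance."""
        means = {c: [] for c in SEVERITY_CLASSES}
        for s in iter_dataset(4, swir, seed=7, height=48, width=48):
            cube = calibrate(s.frames.raw, s.frames.white, s.frames.dark, 0.5)
            roi = cube.values[s.fruit_mask].mean(axis=0)
            means[s.label].append(roi.mean())
        assert (
            np.mean(means["no_drop"])
            > np.mean(means["drop_60"])
            > np.mean(means["drop_100"])
        )

    def test_fruit_roi_mean_matches_analytic_expectation(self, tiny_profile):
        cfg = SceneConfig(height=48, width=48, fruit_center=(24, 24), fruit_radius=15,
                          severity="drop_100", bruise_axes=(6, 5),
                          noise_sd=0.02, seed=31)
        s = render_scene(cfg, generate_endmembers(tiny_profile, "drop_100", 31), tiny_profile)
        cube = calibrate(s.frames.raw, s.frames.white, s.frames.dark, 0.5)
        observed = cube.values[s.fruit_mask].mean(axis=0)
        expected = expected_fruit_roi_spectrum(s)
        se = cfg.noise_sd / np.sqrt(s.fruit_mask.sum())
        # quantization adds a deterministic error floor on top of the noise SE
        assert np.all(np.abs(observed - expected) < 2 * se + 1e-3)

    def test_n_per_class_must_be_positive(self, tiny_profile):
        with pytest.raises(ConfigurationError):
            generate_dataset(0, tiny_profile)
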