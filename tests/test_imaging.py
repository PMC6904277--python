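"""Binarization, particle analysis, biomass, shape and morphometry."""

import dataclasses

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from lblcellfit.imaging import (
    ImagingConfig,
    NoContrastError,
    binarize,
    biomass_series,
    colony_shape_descriptor,
    compare_groups,
    drop_bad_frames,
    label_particles,
    per_cell_measurements,
)
from lblcellfit.presets import COLONY_PRESETS, RenderConfig
from lblcellfit.stacks import ImageStack
from lblcellfit.synthetic_data import simulate_colony_stack
from lblcellfit.synthetic_data.colony import spherocylinder_area


class TestBinarize:
    def test_two_level_image_splits_at_bright_half(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 1000.0
        for method, thr in (("otsu", None), ("fixed", 500.0)):
            bm = binarize(img, method=method, fixed_threshold=thr)
            assert bm.mask[:, 10:].all() and not bm.mask[:, :10].any()

    def test_all_zero_frame_fixed_threshold_empty(self):
        bm = binarize(np.zeros((8, 8)), method="fixed", fixed_threshold=10.0)
        assert not bm.mask.any()

    def test_constant_image_otsu_raises_no_contrast(self):
        with pytest.raises(NoContrastError, match="no contrast"):
            binarize(np.full((8, 8), 7.0), method="otsu")

    def test_fixed_method_requires_threshold(self):
        with pytest.raises(ValueError, match="fixed_threshold"):
            binarize(np.zeros((4, 4)), method="fixed")

    def test_threshold_recorded_in_provenance(self):
        img = np.zeros((10, 10))
        img[3:7, 3:7] = 100.0
        bm = binarize(img, channel="gfp", frame_index=2)
        assert bm.channel == "gfp" and bm.frame_index == 2
        assert 0.0 < bm.threshold < 100.0


class TestSingleRodAccuracy:
    def test_mask_area_close_to_analytic_spherocylinder(self, single_rod_frame):
        img, cell, cfg = single_rod_frame
        bm = binarize(img)
        measured = bm.mask.sum() * cfg.pixel_size**2
        truth = spherocylinder_area(cell.length, cell.width)
        assert measured == pytest.approx(truth, rel=0.15)

    def test_length_and_width_recovered(self, single_rod_frame):
        img, cell, cfg = single_rod_frame
        df = per_cell_measurements(binarize(img), {"gfp": img}, cfg.pixel_size)
        assert len(df) == 1
        assert df["length_um"].iloc[0] == pytest.approx(cell.length, rel=0.10)
        assert df["width_um"].iloc[0] == pytest.approx(cell.width, rel=0.20)


class TestLabelParticles:
    def test_min_area_filters_small_square(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[2:12, 2:12] = True  # 10x10
        mask[20:22, 20:22] = True  # 2x2
        df = label_particles(mask, min_area_px=5)
        assert len(df) == 1
        assert df["area_px"].iloc[0] == 100

    def test_empty_mask_gives_empty_table(self):
        df = label_particles(np.zeros((10, 10), dtype=bool), min_area_px=0)
        assert df.empty

    def test_count_matches_separated_ground_truth(self, small_control_stack):
        stack, truth = small_control_stack
        img = stack.frame("gfp", 0)  # founding cells are well separated
        df = label_particles(binarize(img), min_area_px=5)
        n_true = len(truth.frame_table(0))
        assert len(df) == n_true

    def test_negative_min_area_rejected(self):
        with pytest.raises(ValueError):
            label_particles(np.ones((4, 4), dtype=bool), min_area_px=-1)


class TestBiomassSeries:
    def test_static_scene_constant_series(self):
        preset = dataclasses.replace(
            COLONY_PRESETS["control"], elong_rate=0.0, sd_lag=0.0
        )
        stack, _ = simulate_colony_stack(
            preset, n_cells0=3, duration=30, dt=5,
            render=RenderConfig(noise_sd=0.0), seed=2,
        )
        series = biomass_series(stack)
        assert series["total_area_um2"].nunique() == 1

    def test_series_rises_after_true_lag(self, small_control_stack):
        stack, truth = small_control_stack
        series = biomass_series(stack)
        lag = truth.lag_true_min
        before = series[series["time_min"] <= lag * 0.5]["total_area_um2"]
        after = series[series["time_min"] >= lag + 40]["total_area_um2"]
        assert after.mean() > 1.5 * before.mean()

    def test_area_invariant_to_pixel_size(self):
        preset = dataclasses.replace(COLONY_PRESETS["control"], sd_lag=0.0)
        # same physical field and PSF (0.2 μm), different sampling
        fine = RenderConfig(
            shape=(512, 512), pixel_size=0.1, sigma_psf_px=2.0, noise_sd=0.0
        )
        coarse = RenderConfig(
            shape=(256, 256), pixel_size=0.2, sigma_psf_px=1.0, noise_sd=0.0
        )
        areas = []
        for cfg in (fine, coarse):
            stack, _ = simulate_colony_stack(
                preset, n_cells0=4, duration=10, dt=5, render=cfg, seed=8
            )
            areas.append(biomass_series(stack)["total_area_um2"].iloc[0])
        assert areas[0] == pytest.approx(areas[1], rel=0.10)

    def test_missing_channel_raises(self, small_control_stack):
        stack, _ = small_control_stack
        with pytest.raises(KeyError):
            biomass_series(stack, channel="brightfield")


class TestDropBadFrames:
    @staticmethod
    def _stack_with_blur(blur_index=None, sigma=20.0):
        rng = np.random.default_rng(0)
        frames = []
        for i in range(6):
            img = np.full((64, 64), 100.0)
            img[20:40, 20:30] = 1000.0
            if i == blur_index:
                img = gaussian_filter(img, sigma)
            frames.append(img + rng.normal(0, 2, img.shape))
        return ImageStack(
            frames={"gfp": np.stack(frames)},
            times=np.arange(6.0),
            pixel_size=0.1,
        )

    def test_heavily_blurred_frame_removed(self):
        stack = self._stack_with_blur(blur_index=3)
        kept = drop_bad_frames(stack, contrast_min=0.5, focus_min=0.5)
        assert kept.n_frames == 5
        assert 3.0 not in kept.times

    def test_uniform_quality_stack_is_identity(self):
        stack = self._stack_with_blur(blur_index=None)
        kept = drop_bad_frames(stack, contrast_min=0.5, focus_min=0.5)
        assert kept.n_frames == stack.n_frames

    def test_zero_thresholds_keep_everything(self):
        stack = self._stack_with_blur(blur_index=2)
        kept = drop_bad_frames(stack, contrast_min=0.0, focus_min=0.0)
        assert kept.n_frames == stack.n_frames

    def test_invalid_threshold_rejected(self):
        stack = self._stack_with_blur()
        with pytest.raises(ValueError):
            drop_bad_frames(stack, contrast_min=1.5, focus_min=0.5)


class TestShapeDescriptor:
    def test_disk_scores_near_zero(self):
        yy, xx = np.mgrid[:128, :128]
        disk = (xx - 64) ** 2 + (yy - 64) ** 2 <= 50**2
        assert colony_shape_descriptor(disk) <= 0.1

    def test_elongated_rectangle_matches_closed_form(self):
        rect = np.zeros((40, 140), dtype=bool)
        rect[15:25, 20:120] = True  # 100 x 10 px
        score = colony_shape_descriptor(rect)
        assert score == pytest.approx(1.0 - 4 * np.pi * 1000 / 220.0**2, abs=0.05)

    def test_score_clipped_to_unit_interval(self):
        rng = np.random.default_rng(1)
        ragged = rng.random((64, 64)) > 0.6
        ragged[32, 32] = True
        s = colony_shape_descriptor(ragged)
        assert 0.0 <= s <= 1.0

    def test_invariant_to_rotation_and_translation(self):
        rect = np.zeros((200, 200), dtype=bool)
        rect[90:110, 40:160] = True
        s0 = colony_shape_descriptor(rect)
        assert colony_shape_descriptor(np.rot90(rect)) == pytest.approx(s0, abs=1e-9)
        assert colony_shape_descriptor(np.roll(rect, 17, axis=1)) == pytest.approx(
            s0, abs=1e-9
        )

    def test_monotone_in_ellipse_aspect_ratio(self):
        yy, xx = np.mgrid[:256, :256]
        scores = []
        for aspect in (1.0, 2.0, 3.0, 4.0, 5.0):
            a, b = 40.0 * aspect**0.5, 40.0 / aspect**0.5
            ell = ((xx - 128) / a) ** 2 + ((yy - 128) / b) ** 2 <= 1.0
            scores.append(colony_shape_descriptor(ell))
        assert all(s2 > s1 for s1, s2 in zip(scores, scores[1:]))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            colony_shape_descriptor(np.zeros((10, 10), dtype=bool))


class TestGroupComparison:
    def test_identical_groups_not_significant(self, single_rod_frame):
        img, _, cfg = single_rod_frame
        df = per_cell_measurements(binarize(img), {"gfp": img}, cfg.pixel_size)
        many = df.loc[df.index.repeat(5)].reset_index(drop=True)
        jitter = np.linspace(-0.01, 0.01, len(many))
        many["length_um"] = many["length_um"] + jitter
        comp = compare_groups(many, many.copy(), columns=("length_um",))
        assert comp["p_value"].iloc[0] > 0.5
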