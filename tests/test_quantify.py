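"""Quantitative feature operations: clipping, ROI stats, enhancement, size."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cectfidelity.core import Phase
from cectfidelity.quantify import (
    clip_array,
    clip_hu,
    enhancement_image,
    enhancement_stats,
    image_sd,
    lesion_dimensions,
    roi_intensity_stats,
)
from conftest import make_image, make_study


class TestClip:
    @pytest.mark.parametrize(
        "value, expected", [(1500.0, 1000.0), (-200.0, -150.0), (40.0, 40.0)]
    )
    def test_clip_bounds(self, value, expected):
        img = make_image(np.full((4, 4), value))
        assert clip_hu(img).pixels[0, 0] == expected

    @given(st.floats(-5000, 5000))
    @settings(max_examples=50, deadline=None)
    def test_clip_idempotent(self, v):
        arr = np.array([[v]])
        np.testing.assert_array_equal(clip_array(clip_array(arr)), clip_array(arr))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            clip_array(np.array([[np.inf]]))


class TestRoiStats:
    def test_uniform_roi(self):
        img = make_image(np.full((8, 8), 80.0))
        s = roi_intensity_stats(img, np.ones((8, 8), bool))
        assert (s.min_hu, s.mean_hu, s.max_hu, s.sd_hu) == (80.0, 80.0, 80.0, 0.0)

    def test_clip_then_stats_by_hand(self):
        # pixels {-200, 0, 2000} clip to {-150, 0, 1000}; mean = 850/3
        img = make_image(np.array([[-200.0, 0.0, 2000.0]]))
        s = roi_intensity_stats(img, np.ones((1, 3), bool))
        assert s.min_hu == -150.0
        assert s.max_hu == 1000.0
        assert s.mean_hu == pytest.approx(850.0 / 3.0)
        assert s.n_pixels == 3

    def test_bright_tumor_roi_exceeds_full_image_mean(self, base_study):
        img = base_study[Phase.NEPHROGRAPHIC]
        tumor = roi_intensity_stats(img, base_study.tumor_roi)
        full = roi_intensity_stats(img, np.ones(img.shape, bool))
        assert tumor.mean_hu > full.mean_hu

    def test_order_invariance_under_mask_permutation(self):
        rng = np.random.default_rng(0)
        img = make_image(rng.normal(50, 30, (12, 12)))
        roi = rng.random((12, 12)) > 0.5
        s = roi_intensity_stats(img, roi)
        flipped = make_image(img.pixels[::-1, ::-1].copy())
        s2 = roi_intensity_stats(flipped, roi[::-1, ::-1])
        assert (s.min_hu, s.max_hu, s.n_pixels) == (s2.min_hu, s2.max_hu, s2.n_pixels)
        assert s.mean_hu == pytest.approx(s2.mean_hu, rel=1e-14)
        assert s.sd_hu == pytest.approx(s2.sd_hu, rel=1e-12)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_intensity_stats(make_image(np.zeros((4, 4))), np.zeros((4, 4), bool))


class TestEnhancement:
    def test_self_difference_is_zero(self):
        pre = make_image(np.full((4, 4), 30.0), Phase.PRECONTRAST)
        post = make_image(np.full((4, 4), 30.0), Phase.NEPHROGRAPHIC)
        np.testing.assert_array_equal(enhancement_image(post, pre), np.zeros((4, 4)))

    def test_uniform_difference(self):
        pre = make_image(np.full((4, 4), 30.0), Phase.PRECONTRAST)
        post = make_image(np.full((4, 4), 80.0), Phase.CORTICOMEDULLARY)
        np.testing.assert_array_equal(enhancement_image(post, pre), np.full((4, 4), 50.0))

    def test_clip_before_subtract_extremes(self):
        # -200 clips to -150, 1200 clips to 1000 -> difference 1150
        pre = make_image(np.array([[-200.0]]), Phase.PRECONTRAST)
        post = make_image(np.array([[1200.0]]), Phase.EXCRETORY)
        assert enhancement_image(post, pre)[0, 0] == 1150.0

    def test_precontrast_as_post_rejected(self):
        pre = make_image(np.zeros((2, 2)), Phase.PRECONTRAST)
        with pytest.raises(ValueError):
            enhancement_image(pre, pre)

    def test_phantom_mean_enhancement_matches_phase_curve(self, base_study, base_spec):
        s = enhancement_stats(base_study, Phase.CORTICOMEDULLARY)
        expected = base_spec.phase_curve[1] - base_spec.phase_curve[0]
        assert s.mean_enh == pytest.approx(expected)
        assert s.min_enh == pytest.approx(expected)


class TestLesionDimensions:
    def test_circle_diameter(self):
        rr, cc = np.ogrid[:32, :32]
        disk = (rr - 16) ** 2 + (cc - 16) ** 2 <= 10**2
        size = lesion_dimensions(disk, spacing=1.0)
        assert size.d1 == pytest.approx(20.0, abs=1.0)
        assert size.d2 == pytest.approx(20.0, abs=1.0)

    def test_ellipse_axes(self):
        rr, cc = np.ogrid[:48, :48]
        ell = ((rr - 24) / 15.0) ** 2 + ((cc - 24) / 5.0) ** 2 <= 1.0
        size = lesion_dimensions(ell, spacing=1.0)
        assert size.d1 == pytest.approx(30.0, abs=1.0)
        assert size.d2 == pytest.approx(10.0, abs=1.0)

    def test_single_pixel_convention(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        size = lesion_dimensions(m, spacing=0.7)
        assert size.d1 == size.d2 == 0.7

    def test_scales_linearly_with_spacing(self):
        rr, cc = np.ogrid[:32, :32]
        disk = (rr - 16) ** 2 + (cc - 16) ** 2 <= 8**2
        a = lesion_dimensions(disk, spacing=1.0)
        b = lesion_dimensions(disk, spacing=2.5)
        assert b.d1 == pytest.approx(2.5 * a.d1)
        assert b.d2 == pytest.approx(2.5 * a.d2)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_d1_matches_exhaustive_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((20, 20), bool)
        n_blobs = rng.integers(1, 4)
        for _ in range(n_blobs):
            r, c = rng.integers(3, 17, 2)
            rad = rng.integers(1, 4)
            rr, cc = np.ogrid[:20, :20]
            mask |= (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
        assert mask.sum() <= 500
        coords = np.argwhere(mask).astype(float)
        brute = 0.0
        for i in range(len(coords)):
            d = np.hypot(*(coords - coords[i]).T).max()
            brute = max(brute, d)
        assert lesion_dimensions(mask).d1 == pytest.approx(max(brute, 1.0))


class TestImageSd:
    def test_constant_image(self):
        img = make_image(np.full((6, 6), 42.0))
        assert image_sd(img, np.ones((6, 6), bool)) == 0.0

    def test_population_sd_by_hand(self):
        img = make_image(np.array([[0.0, 0.0], [10.0, 10.0]]))
        assert image_sd(img, np.ones((2, 2), bool)) == 5.0

    def test_damped_surrogate_sd_not_above_gt(self):
        from cectfidelity.phantom import DegradationSpec, PhantomSpec, apply_degradation, render_phantom

        study = render_phantom(PhantomSpec(heterogeneity=40.0), seed=2)
        surr = apply_degradation(
            study, Phase.NEPHROGRAPHIC, DegradationSpec(heterogeneity_damping=0.5)
        )
        roi = study.tumor_roi
        assert image_sd(surr, roi) <= image_sd(study[Phase.NEPHROGRAPHIC], roi)

    def test_full_crop_region(self):
        img = make_image(np.arange(16.0).reshape(4, 4))
        assert image_sd(img, region="full_crop") == pytest.approx(np.arange(16.0).std())
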