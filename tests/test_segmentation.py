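"""Segmentation stages on analytic and phantom volumes."""

import numpy as np
import pytest

from vasculograph import (
    BinaryMask,
    VolumeImage,
    enhance_vessels,
    extract_region,
    region_grow,
    threshold_segment,
    transform_gray,
)
from vasculograph.segmentation import DegenerateHistogramError


def _vol(values):
    return VolumeImage(np.asarray(values, np.float32), 4.5)


class TestExtractRegion:
    def test_all_true_roi_is_identity(self):
        vol = _vol(np.random.default_rng(0).uniform(0, 100, (8, 8, 8)))
        roi = BinaryMask(np.ones((8, 8, 8), bool), 4.5)
        assert np.array_equal(extract_region(vol, roi).values, vol.values)

    def test_all_false_roi_zeroes_volume(self):
        vol = _vol(np.full((8, 8, 8), 50.0))
        roi = BinaryMask(np.zeros((8, 8, 8), bool), 4.5)
        assert not extract_region(vol, roi).values.any()

    def test_half_plane_roi(self):
        vol = _vol(np.full((8, 8, 8), 100.0))
        roi = np.zeros((8, 8, 8), bool)
        roi[:4] = True
        out = extract_region(vol, BinaryMask(roi, 4.5))
        assert (out.values == 100.0).sum() == 4 * 8 * 8

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_region(_vol(np.zeros((8, 8, 8))), BinaryMask(np.ones((4, 8, 8), bool), 4.5))


class TestTransformGray:
    def test_full_span_maps_min_to_0_max_to_1(self):
        rng = np.random.default_rng(1)
        vol = _vol(rng.uniform(10, 90, (16, 16, 16)))
        out = transform_gray(vol, 0, 100)
        assert out.values.min() == pytest.approx(0.0, abs=1e-6)
        assert out.values.max() == pytest.approx(1.0, abs=1e-6)

    def test_constant_volume_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = transform_gray(_vol(np.full((8, 8, 8), 3.0)))
        assert not out.values.any()

    def test_uniform_ramp_mean_is_half(self):
        ramp = np.linspace(0, 100, 16 * 16 * 16, dtype=np.float32).reshape(16, 16, 16)
        out = transform_gray(VolumeImage(ramp, 4.5), 0, 100)
        assert out.values.mean() == pytest.approx(0.5, abs=0.01)

    def test_invalid_percentiles_rejected(self):
        with pytest.raises(ValueError):
            transform_gray(_vol(np.zeros((8, 8, 8))), 60, 40)


class TestEnhanceVessels:
    def test_zero_volume_gives_zero_response(self):
        out = enhance_vessels(_vol(np.zeros((32, 32, 32))))
        assert not out.values.any()

    def test_tube_beats_background(self):
        # straight tube, radius 3 voxels, running along the z axis
        z, y, x = np.meshgrid(*[np.arange(48)] * 3, indexing="ij")
        v = np.where((y - 24) ** 2 + (x - 24) ** 2 <= 3**2, 200.0, 0.0).astype(np.float32)
        resp = enhance_vessels(VolumeImage(v, 4.5), (9.0, 13.5, 18.0))
        centerline = resp.values[4:44, 24, 24].mean()
        background = resp.values[:, 4, 4].mean()
        assert centerline > 5 * max(background, 1e-12)

    def test_tube_discriminated_from_ball(self):
        v = np.zeros((64, 64, 64), np.float32)
        z, y, x = np.meshgrid(*[np.arange(64)] * 3, indexing="ij")
        ball = (z - 20) ** 2 + (y - 20) ** 2 + (x - 20) ** 2 <= 10**2
        tube = (z - 48) ** 2 + (y - 48) ** 2 <= 3**2
        v[ball] = 200.0
        v[tube] = 200.0
        resp = enhance_vessels(VolumeImage(v, 4.5), (13.5,))
        ball_interior = resp.values[(z - 20) ** 2 + (y - 20) ** 2 + (x - 20) ** 2 <= 5**2]
        tube_centerline = resp.values[48, 48, 8:56]
        assert ball_interior.mean() < tube_centerline.mean()

    def test_empty_scales_rejected(self):
        with pytest.raises(ValueError):
            enhance_vessels(_vol(np.zeros((32, 32, 32))), [])

    def test_oversized_scale_warns(self):
        with pytest.warns(UserWarning):
            enhance_vessels(_vol(np.ones((20, 20, 20))), [100.0])


class TestThresholdSegment:
    def test_fixed_threshold_on_binary_volume(self):
        rng = np.random.default_rng(2)
        v = rng.choice([0.0, 100.0], size=(16, 16, 16)).astype(np.float32)
        mask = threshold_segment(_vol(v), method="fixed", value=50)
        assert np.array_equal(mask.values, v == 100.0)

    def test_fixed_at_max_gives_empty_mask(self):
        v = np.full((8, 8, 8), 9.0, np.float32)
        assert threshold_segment(_vol(v), "fixed", 9.0).count() == 0

    def test_otsu_on_bimodal_mixture(self):
        rng = np.random.default_rng(3)
        labels = rng.random((32, 32, 32)) < 0.5
        v = np.where(labels, rng.normal(200, 10, labels.shape), rng.normal(20, 10, labels.shape))
        mask = threshold_segment(_vol(v))
        misclassified = np.mean(mask.values != labels)
        assert misclassified < 0.01

    def test_otsu_on_constant_volume_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            threshold_segment(_vol(np.full((8, 8, 8), 1.0)))

    def test_threshold_recorded_in_provenance(self):
        mask = threshold_segment(_vol(np.arange(64, dtype=np.float32).reshape(4, 4, 4)))
        assert "threshold" in mask.provenance

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        vol = _vol(rng.uniform(0, 1, (12, 12, 12)))
        low = threshold_segment(vol, "fixed", 0.3).values
        high = threshold_segment(vol, "fixed", 0.6).values
        assert np.all(high <= low)  # raising threshold never adds voxels


class TestRegionGrow:
    def test_homogeneous_component_recovered_exactly(self):
        v = np.zeros((16, 16, 16), np.float32)
        v[4:8, 4:8, 4:8] = 100.0
        v[12:15, 12:15, 12:15] = 100.0  # second, unseeded component
        mask = BinaryMask(v > 50, 4.5)
        out = region_grow(mask, _vol(v), seeds=[(5, 5, 5)], tol=10.0)
        expected = np.zeros_like(v, bool)
        expected[4:8, 4:8, 4:8] = True
        assert np.array_equal(out.values, expected)

    def test_zero_tolerance_no_growth_on_noise(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0, 100, (12, 12, 12)).astype(np.float32)
        mask = BinaryMask(v > 60, 4.5)
        seed = tuple(np.argwhere(mask.values)[0])
        out = region_grow(mask, _vol(v), seeds=[seed], tol=0.0)
        from scipy import ndimage

        labels, _ = ndimage.label(mask.values, structure=np.ones((3, 3, 3), bool))
        assert np.array_equal(out.values, labels == labels[seed])

    def test_bridges_one_voxel_intensity_dip(self):
        v = np.zeros((7, 7, 21), np.float32)
        v[2:5, 2:5, 2:19] = 100.0
        v[2:5, 2:5, 10] = 50.0  # dip splits the threshold mask
        mask = threshold_segment(_vol(v), "fixed", 75.0)
        from scipy import ndimage

        struct = np.ones((3, 3, 3), bool)
        assert ndimage.label(mask.values, structure=struct)[1] == 2
        out = region_grow(mask, _vol(v), seeds=[(3, 3, 4)], tol=60.0)
        assert ndimage.label(out.values, structure=struct)[1] == 1
        assert out.values[3, 3, 10]

    def test_no_seeds_warns_and_returns_mask(self):
        v = np.zeros((8, 8, 8), np.float32)
        mask = BinaryMask(v > 1, 4.5)
        with pytest.warns(UserWarning):
            out = region_grow(mask, _vol(v), seeds=[], tol=1.0)
        assert np.array_equal(out.values, mask.values)

    def test_seed_outside_grid_rejected(self):
        v = np.zeros((8, 8, 8), np.float32)
        with pytest.raises(ValueError):
            region_grow(BinaryMask(v > 1, 4.5), _vol(v), seeds=[(9, 0, 0)], tol=1.0)
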