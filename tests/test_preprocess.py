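"""Z-score normalization and isotropic resampling of images and masks."""

import numpy as np
import pytest
from scipy import ndimage

from gliorad.exceptions import DegenerateIntensity, EmptyRoi
from gliorad.image import RoiMask, VolumeImage
from gliorad.preprocess import (
    resample_image_isotropic,
    resample_mask_isotropic,
    zscore_normalize,
)


def _vol(arr, spacing=(1, 1, 1)):
    return VolumeImage(np.asarray(arr, dtype=float), spacing)


def _full_mask(shape, spacing=(1, 1, 1)):
    return RoiMask(np.ones(shape, bool), spacing)


class TestZscore:
    def test_three_point_symmetric_case(self):
        img = _vol(np.array([2.0, 4.0, 6.0]).reshape(1, 1, 3))
        out = zscore_normalize(img, _full_mask((1, 1, 3)))
        np.testing.assert_allclose(
            out.values.ravel(), [-1.224744871, 0.0, 1.224744871], atol=1e-9
        )
        assert out.normalization == "zscored"

    def test_within_mask_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        img = _vol(rng.normal(100, 17, (8, 8, 8)))
        mask = RoiMask(rng.random((8, 8, 8)) < 0.6)
        out = zscore_normalize(img, mask)
        inside = out.values[mask.values]
        assert abs(inside.mean()) < 1e-10
        assert abs(inside.std() - 1) < 1e-10

    def test_outside_mask_uses_same_transform(self):
        img = _vol(np.arange(64.0).reshape(4, 4, 4))
        mask = RoiMask(np.pad(np.ones((2, 2, 2), bool), 1))
        out = zscore_normalize(img, mask)
        inside = img.values[mask.values]
        mu, sd = inside.mean(), inside.std()
        np.testing.assert_allclose(out.values, (img.values - mu) / sd)

    def test_idempotent_fixed_point(self):
        rng = np.random.default_rng(1)
        img = _vol(rng.normal(0, 3, (6, 6, 6)))
        mask = _full_mask((6, 6, 6))
        once = zscore_normalize(img, mask)
        twice = zscore_normalize(once, mask)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateIntensity):
            zscore_normalize(_vol(np.ones((4, 4, 4))), _full_mask((4, 4, 4)))

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyRoi):
            zscore_normalize(
                _vol(np.ones((4, 4, 4))), RoiMask(np.zeros((4, 4, 4), bool))
            )


class TestResampleImage:
    def test_identity_grid(self):
        rng = np.random.default_rng(2)
        img = _vol(rng.normal(size=(10, 11, 12)))
        out = resample_image_isotropic(img, 1.0)
        assert out.shape == img.shape
        np.testing.assert_allclose(out.values, img.values, atol=1e-9)

    def test_constant_anisotropic(self):
        img = _vol(np.full((6, 8, 10), 3.25), spacing=(2.0, 1.5, 0.7))
        out = resample_image_isotropic(img, 1.0)
        np.testing.assert_allclose(out.values, 3.25, atol=1e-9)
        assert out.spacing == (1.0, 1.0, 1.0)

    def test_linear_ramp_halved_step(self):
        """f(x) = x at 2 mm resampled to 1 mm: ramp with halved step, tiny
        interpolation error away from boundaries (closed-form oracle)."""
        nx = 40
        ramp = np.broadcast_to(
            np.arange(nx, dtype=float)[:, None, None], (nx, 6, 6)
        ).copy()
        img = _vol(ramp, spacing=(2.0, 1.0, 1.0))
        out = resample_image_isotropic(img, 1.0)
        assert out.shape[0] == 2 * nx
        expect = np.arange(out.shape[0]) * 0.5  # old-index units
        err = np.abs(out.values[:, 3, 3] - expect)
        # spline edge effects decay geometrically from the faces; the
        # interior (>= 12 old voxels from either face) is exact to 1e-6
        assert err[24:-24].max() < 1e-6

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            resample_image_isotropic(_vol(np.zeros((4, 4, 4))), -1.0)


class TestResampleMask:
    def test_identity(self):
        m = RoiMask(np.pad(np.ones((2, 2, 2), bool), 2))
        out = resample_mask_isotropic(m, 1.0)
        assert np.array_equal(out.values, m.values)

    def test_single_voxel_upsampled(self):
        """2 mm single voxel -> 1 mm grid: non-empty 26-connected blob with
        centroid within 1 mm of the original voxel centre."""
        arr = np.zeros((5, 5, 5), bool)
        arr[2, 2, 2] = True
        out = resample_mask_isotropic(RoiMask(arr, (2.0, 2.0, 2.0)), 1.0)
        assert out.values.any()
        assert out.values.dtype == bool
        _, n = ndimage.label(out.values, structure=np.ones((3, 3, 3)))
        assert n == 1
        centroid_mm = np.argwhere(out.values).mean(axis=0) * 1.0
        orig_mm = np.array([2, 2, 2]) * 2.0
        assert np.linalg.norm(centroid_mm - orig_mm) < 1.0

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyRoi):
            resample_mask_isotropic(RoiMask(np.zeros((4, 4, 4), bool), (2, 2, 2)), 1.0)

    @pytest.mark.parametrize("radius", [3, 5, 8])
    def test_sphere_topology_and_volume(self, radius):
        n = 2 * radius + 7
        g = np.indices((n, n, n)) - n // 2
        sphere = (g**2).sum(axis=0) <= radius**2
        out = resample_mask_isotropic(RoiMask(sphere, (1.3, 1.3, 1.3)), 1.0)
        _, ncomp = ndimage.label(out.values, structure=np.ones((3, 3, 3)))
        assert ncomp == 1
        if radius >= 5:
            vol_in = sphere.sum() * 1.3**3
            vol_out = out.values.sum() * 1.0
            assert abs(vol_out - vol_in) / vol_in < 0.15
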