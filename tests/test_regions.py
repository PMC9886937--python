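"""CTV expansion, mask-and-crop, black-border cropping and augmentation."""

import numpy as np
import pytest
from scipy import ndimage

from pelvidet import (
    AugmentParams,
    Slice25D,
    augment,
    crop_black_border,
    expand_mask,
    mask_and_crop,
    stack_25d,
)
from pelvidet.regions import EmptyRegionError
from conftest import make_mask, make_volume


def slab(h=32, w=32, nz=3, fill=0.0):
    return make_volume(np.full((nz, h, w), fill))


class TestExpandMask:
    def test_zero_is_identity(self):
        vol = slab()
        m = np.zeros((3, 32, 32))
        m[1, 10:14, 10:14] = 1
        out = expand_mask(make_mask(m, "ctv", vol), 0)
        np.testing.assert_array_equal(out.mask, m.astype(bool))
        assert out.role == "ctv_expanded"

    def test_single_pixel_radius_one_is_plus_shape(self):
        vol = slab()
        m = np.zeros((3, 32, 32))
        m[1, 16, 16] = 1
        out = expand_mask(make_mask(m, "ctv", vol), 1)
        expected = {(16, 16), (15, 16), (17, 16), (16, 15), (16, 17)}
        assert {tuple(p) for p in np.argwhere(out.mask[1])} == expected
        assert not out.mask[0].any() and not out.mask[2].any()

    def test_matches_distance_transform_at_10px(self):
        rng = np.random.default_rng(2)
        vol = slab(48, 48)
        m = np.zeros((3, 48, 48))
        m[1][tuple(rng.integers(12, 36, size=(5, 2)).T)] = 1
        out = expand_mask(make_mask(m, "ctv", vol), 10)
        dist = ndimage.distance_transform_edt(~m[1].astype(bool))
        np.testing.assert_array_equal(out.mask[1], dist <= 10)

    def test_monotone_nested_in_k(self):
        vol = slab()
        m = np.zeros((3, 32, 32))
        m[1, 14:18, 14:18] = 1
        lv = make_mask(m, "ctv", vol)
        prev = expand_mask(lv, 0).mask
        for k in (1, 3, 6, 10):
            cur = expand_mask(lv, k).mask
            assert np.all(prev <= cur)
            prev = cur

    def test_negative_rejected(self):
        vol = slab()
        with pytest.raises(ValueError):
            expand_mask(make_mask(np.zeros((3, 32, 32)), "ctv", vol), -1)


class TestMaskAndCrop:
    def test_full_mask_is_identity(self):
        vol = make_volume(np.random.default_rng(0).normal(40, 10, (3, 16, 16)))
        s = stack_25d(vol, 1)
        expanded = make_mask(np.ones((3, 16, 16)), "ctv_expanded", vol)
        out = mask_and_crop(s, expanded)
        np.testing.assert_array_equal(out.channels, s.channels)
        assert out.crop_offset == (0, 0)

    def test_crop_geometry_and_zeroing(self):
        vox = np.full((3, 64, 64), 300.0)
        vol = make_volume(vox)
        m = np.zeros((3, 64, 64))
        m[1, 10:21, 30:51] = 1
        expanded = make_mask(m, "ctv_expanded", vol)
        out = mask_and_crop(stack_25d(vol, 1), expanded)
        assert out.channels.shape == (3, 11, 21)
        assert out.crop_offset == (10, 30)
        # inside the mask values survive; a 300 HU pixel outside is zeroed
        assert np.all(out.channels == 300.0)
        m2 = m.copy()
        m2[1, 15, 40] = 0
        out2 = mask_and_crop(stack_25d(vol, 1), make_mask(m2, "ctv_expanded", vol))
        assert out2.channels[1, 5, 10] == 0.0

    def test_never_increases_values(self):
        rng = np.random.default_rng(4)
        vol = make_volume(np.abs(rng.normal(100, 50, (3, 32, 32))))
        m = np.zeros((3, 32, 32))
        m[1, 8:24, 8:24] = rng.random((16, 16)) < 0.5
        if not m[1].any():
            m[1, 10, 10] = 1
        out = mask_and_crop(stack_25d(vol, 1), make_mask(m, "ctv_expanded", vol))
        r0, c0 = out.crop_offset
        h, w = out.channels.shape[1:]
        np.testing.assert_array_compare(
            np.less_equal, out.channels, vol.voxels[:3, r0 : r0 + h, c0 : c0 + w] + 1e-12
        )

    def test_empty_central_slice_signalled(self):
        vol = slab()
        m = np.zeros((3, 32, 32))
        m[0, 5, 5] = 1  # present, but not on the central slice
        with pytest.raises(EmptyRegionError):
            mask_and_crop(stack_25d(vol, 1), make_mask(m, "ctv_expanded", vol))


class TestCropBlackBorder:
    def _framed(self, pad=7):
        img = np.full((3, 20 + 2 * pad, 24 + 2 * pad), -1024.0)
        img[:, pad : pad + 20, pad : pad + 24] = 40.0
        return Slice25D(channels=img, center_index=0)

    def test_removes_air_margin(self):
        out = crop_black_border(self._framed(7))
        assert out.channels.shape == (3, 20, 24)
        assert out.crop_offset == (7, 7)

    def test_identity_without_margin_and_idempotent(self):
        s = Slice25D(channels=np.full((3, 8, 8), 30.0), center_index=0)
        out = crop_black_border(s)
        np.testing.assert_array_equal(out.channels, s.channels)
        twice = crop_black_border(crop_black_border(self._framed()))
        once = crop_black_border(self._framed())
        np.testing.assert_array_equal(twice.channels, once.channels)
        assert twice.crop_offset == once.crop_offset

    def test_fully_black_flagged(self):
        s = Slice25D(channels=np.full((3, 8, 8), -1024.0), center_index=0)
        out = crop_black_border(s)
        assert "all_black" in out.flags
        assert out.channels.shape == (3, 8, 8)


class TestAugment:
    def _sample(self, h=100, w=50):
        img = np.zeros((3, h, w))
        img[:, 30:60, 10:30] = 1.0
        boxes = np.array([[10.0, 30.0, 30.0, 60.0]])
        return Slice25D(channels=img, center_index=0), boxes

    def test_deterministic_given_seed(self):
        s, boxes = self._sample()
        p = AugmentParams(seed=123)
        out1, b1 = augment(s, boxes, p)
        out2, b2 = augment(s, boxes, p)
        np.testing.assert_array_equal(out1.channels, out2.channels)
        np.testing.assert_array_equal(b1, b2)

    def test_pure_resize_scales_boxes(self):
        s, boxes = self._sample(400, 200)
        p = AugmentParams(resize_min=800, resize_max=800, hflip_p=0.0,
                          rotate_max_deg=0.0, noise_amp=0.0, brightness_delta_max=0.0,
                          seed=0)
        out, b = augment(s, boxes, p)
        assert out.channels.shape == (3, 800, 400)
        np.testing.assert_allclose(b, boxes * 2)

    def test_hflip_coordinate_algebra(self):
        s, boxes = self._sample(100, 50)
        p = AugmentParams(resize_min=100, resize_max=100, hflip_p=1.0,
                          rotate_max_deg=0.0, noise_amp=0.0, brightness_delta_max=0.0,
                          seed=0)
        _, b = augment(s, boxes, p)
        x0, y0, x1, y1 = boxes[0]
        np.testing.assert_allclose(b[0], [50 - x1, y0, 50 - x0, y1])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_boxes_track_transformed_pixels(self, seed):
        # the augmented box must tightly contain the warped rectangle:
        # compare with the tight box of the thresholded augmented image
        s, boxes = self._sample(120, 90)
        p = AugmentParams(resize_min=200, resize_max=260, noise_amp=0.0,
                          brightness_delta_max=0.0, seed=seed)
        out, b = augment(s, boxes, p)
        body = out.channels[1] > 0.5
        ys = np.flatnonzero(body.any(axis=1))
        xs = np.flatnonzero(body.any(axis=0))
        ref = (xs[0], ys[0], xs[-1] + 1, ys[-1] + 1)
        from pelvidet import iou

        assert iou(tuple(b[0]), ref) >= 0.9
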