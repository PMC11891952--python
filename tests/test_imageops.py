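"""Unit and property tests for the grayscale/binary primitives."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from aponecv import imageops


def brute_force_ball_opening(img, radius):
    """Loop-based grayscale opening with a non-flat ball (nearest border)."""
    r = radius
    h, w = img.shape
    offsets = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            d2 = dx * dx + dy * dy
            if d2 <= r * r:
                offsets.append((dy, dx, np.sqrt(r * r - d2)))

    def clamp(v, n):
        return min(max(v, 0), n - 1)

    eroded = np.empty_like(img, dtype=float)
    for y in range(h):
        for x in range(w):
            eroded[y, x] = min(img[clamp(y + dy, h), clamp(x + dx, w)] - z
                               for dy, dx, z in offsets)
    opened = np.empty_like(eroded)
    for y in range(h):
        for x in range(w):
            opened[y, x] = max(eroded[clamp(y + dy, h), clamp(x + dx, w)] + z
                               for dy, dx, z in offsets)
    return opened


class TestSubtractBackground:
    def test_constant_image_fully_removed(self):
        img = np.full((40, 40), 40, dtype=np.uint8)
        for radius in (1, 5, 50):
            assert (imageops.subtract_background(img, radius) == 0).all()

    def test_impulse_above_flat_background_survives(self):
        img = np.full((64, 64), 40, dtype=np.uint8)
        img[30, 30] = 240
        out = imageops.subtract_background(img, 50)
        assert abs(int(out[30, 30]) - 200) <= 5
        far = out[:10, :10]
        assert far.max() <= 5

    def test_matches_brute_force_opening_oracle(self, rng):
        img = (rng.uniform(0, 200, (32, 32))
               + np.linspace(0, 55, 32)[None, :])
        radius = 5
        expected = np.clip(img - brute_force_ball_opening(img, radius), 0, None)
        out = imageops.subtract_background(img, radius)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_linear_ramp_matches_oracle(self):
        img = np.tile(np.linspace(0, 126, 48), (48, 1))
        expected = np.clip(img - brute_force_ball_opening(img, 10), 0, None)
        out = imageops.subtract_background(img, 10)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            imageops.subtract_background(np.zeros((5, 5)), 0)


class TestSmooth:
    def test_constant_is_fixed_point(self):
        img = np.full((9, 9), 7.0)
        np.testing.assert_allclose(imageops.smooth(img), img)

    def test_interior_impulse_spreads_to_patch(self):
        img = np.zeros((9, 9))
        img[4, 4] = 90.0
        out = imageops.smooth(img)
        np.testing.assert_allclose(out[3:6, 3:6], 10.0)
        assert out[0, 0] == 0.0

    def test_matches_per_pixel_mean_oracle(self, rng):
        img = rng.uniform(0, 255, (8, 8))
        out = imageops.smooth(img)
        for y in range(8):
            for x in range(8):
                vals = [img[yy, xx]
                        for yy in range(max(y - 1, 0), min(y + 2, 8))
                        for xx in range(max(x - 1, 0), min(x + 2, 8))]
                assert out[y, x] == pytest.approx(np.mean(vals))


class TestBinaryMorphology:
    def test_dilate_single_pixel_gives_block(self):
        m = np.zeros((7, 7), bool)
        m[3, 3] = True
        out = imageops.dilate(m, 1)
        expected = np.zeros((7, 7), bool)
        expected[2:5, 2:5] = True
        assert (out == expected).all()

    def test_erode_block_gives_centre(self):
        m = np.zeros((7, 7), bool)
        m[2:5, 2:5] = True
        out = imageops.erode(m, 1)
        assert out.sum() == 1 and out[3, 3]

    def test_closing_covers_original(self, rng):
        # for masks whose components are at least 3x3 blocks
        for _ in range(20):
            m = np.zeros((16, 16), bool)
            for _ in range(3):
                y, x = rng.integers(0, 13, 2)
                m[y:y + 3, x:x + 3] = True
            closed = imageops.erode(imageops.dilate(m, 1), 1)
            assert (m <= closed).all()

    def test_monotonicity(self, rng):
        m2 = rng.random((20, 20)) < 0.4
        m1 = m2 & (rng.random((20, 20)) < 0.7)  # m1 subset of m2
        for op in (imageops.dilate, imageops.erode):
            assert (op(m1, 1) <= op(m2, 1)).all()


class TestFillHoles:
    def test_ring_becomes_disk(self):
        yy, xx = np.mgrid[-10:11, -10:11]
        d = np.hypot(yy, xx)
        ring = (d <= 8) & (d >= 5)
        filled = imageops.fill_holes(ring)
        assert (filled == (d <= 8)).all()

    def test_no_holes_is_identity(self, rng):
        m = ndi.binary_dilation(rng.random((20, 20)) < 0.1)
        m = imageops.fill_holes(m)  # normalise
        assert (imageops.fill_holes(m) == m).all()

    def test_matches_border_flood_fill_oracle(self, rng):
        m = ndi.binary_closing(rng.random((24, 24)) < 0.45)
        filled = imageops.fill_holes(m)
        # oracle: 4-connected background regions touching the border stay
        bg_labels, _ = ndi.label(~m)  # default structure = 4-connectivity
        border = np.zeros_like(m)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        outside = np.isin(bg_labels, np.unique(bg_labels[border & ~m]))
        expected = m | (~m & ~outside)
        assert (filled == expected).all()


class TestWatershedSplit:
    @staticmethod
    def _disk(shape, cy, cx, r):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r

    def _n_components(self, m):
        return ndi.label(m, structure=np.ones((3, 3)))[1]

    def test_fused_disk_pair_splits_in_two(self):
        m = self._disk((48, 48), 24, 17, 8) | self._disk((48, 48), 24, 31, 8)
        assert self._n_components(m) == 1
        out = imageops.watershed_split(m)
        assert self._n_components(out) == 2

    def test_single_disk_unchanged(self):
        m = self._disk((32, 32), 16, 16, 9)
        out = imageops.watershed_split(m)
        assert (out == m).all()

    def test_empty_mask(self):
        m = np.zeros((10, 10), bool)
        assert not imageops.watershed_split(m).any()

    def test_never_adds_foreground_never_merges(self, rng):
        for _ in range(10):
            m = ndi.binary_closing(rng.random((40, 40)) < 0.35)
            out = imageops.watershed_split(m)
            assert (out <= m).all()
            assert self._n_components(out) >= self._n_components(m)

    def test_split_pieces_are_8_separated(self):
        m = self._disk((48, 64), 24, 20, 9) | self._disk((48, 64), 24, 36, 9)
        out = imageops.watershed_split(m)
        assert self._n_components(out) == 2


class TestMaskAlgebra:
    def test_idempotence_and_annihilation(self, rng):
        a = rng.random((12, 12)) < 0.5
        assert (imageops.mask_and(a, a) == a).all()
        assert not imageops.mask_subtract(a, a).any()

    def test_identity_elements(self, rng):
        a = rng.random((12, 12)) < 0.5
        empty = np.zeros_like(a)
        assert not imageops.mask_and(a, empty).any()
        assert (imageops.mask_subtract(a, empty) == a).all()

    def test_partition_property(self, rng):
        for _ in range(25):
            a = rng.random((16, 16)) < 0.5
            b = rng.random((16, 16)) < 0.5
            inter = imageops.mask_and(a, b)
            diff = imageops.mask_subtract(a, b)
            assert not (inter & diff).any()
            assert ((inter | diff) == a).all()

    def test_subtract_is_and_with_complement(self, rng):
        a = rng.random((16, 16)) < 0.5
        b = rng.random((16, 16)) < 0.5
        lhs = imageops.mask_subtract(a, b)
        rhs = imageops.mask_and(a, imageops.complement(b))
        assert (lhs == rhs).all()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            imageops.mask_and(np.zeros((3, 3), bool), np.zeros((4, 4), bool))
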