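"""Colour conversion and pixel-classification tests."""

import colorsys

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from her2feat import (
    RGBTile,
    HSVImage,
    rgb_to_hsv,
    rgb_to_lab,
    roi_mask,
    stain_mask,
    roi_fraction,
    filter_tiles,
)

from conftest import hsv_tile


def _single_pixel_tile(r, g, b):
    return RGBTile(pixels=np.full((3, 3, 3), (r, g, b), dtype=np.uint8))


class TestRGBToHSV:
    @pytest.mark.parametrize("rgb, expected_hsv", [
        ((255, 0, 0), (0.0, 1.0, 1.0)),        # primary-colour identity
        ((255, 255, 255), (0.0, 0.0, 1.0)),    # achromatic: S = 0, hue defined 0
        ((128, 64, 0), (30.0, 1.0, 128 / 255)),
    ])
    def test_known_pixels(self, rgb, expected_hsv):
        hsv = rgb_to_hsv(_single_pixel_tile(*rgb))
        h, s, v = expected_hsv
        assert hsv.hue[0, 0] == pytest.approx(h, abs=1e-6)
        assert hsv.saturation[0, 0] == pytest.approx(s, abs=1e-6)
        assert hsv.value[0, 0] == pytest.approx(v, abs=1e-6)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255))
    def test_matches_stdlib_reference(self, r, g, b):
        """Conversion agrees with the independent colorsys implementation."""
        hsv = rgb_to_hsv(_single_pixel_tile(r, g, b))
        h, s, v = colorsys.rgb_to_hsv(r / 255, g / 255, b / 255)
        assert hsv.hue[0, 0] == pytest.approx(h * 360.0, abs=1e-6)
        assert hsv.saturation[0, 0] == pytest.approx(s, abs=1e-6)
        assert hsv.value[0, 0] == pytest.approx(v, abs=1e-6)


def _reference_lab(r, g, b):
    """Hand-rolled sRGB (D65) -> CIE-Lab, independent of scikit-image."""
    def linearize(c):
        c = c / 255.0
        return c / 12.92 if c <= 0.04045 else ((c + 0.055) / 1.055) ** 2.4
    rl, gl, bl = (linearize(c) for c in (r, g, b))
    X = 0.4124564 * rl + 0.3575761 * gl + 0.1804375 * bl
    Y = 0.2126729 * rl + 0.7151522 * gl + 0.0721750 * bl
    Z = 0.0193339 * rl + 0.1191920 * gl + 0.9503041 * bl
    Xn, Yn, Zn = 0.95047, 1.0, 1.08883
    def f(t):
        return t ** (1 / 3) if t > (6 / 29) ** 3 else t / (3 * (6 / 29) ** 2) + 4 / 29
    fx, fy, fz = f(X / Xn), f(Y / Yn), f(Z / Zn)
    return 116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz)


class TestRGBToLab:
    def test_white_point(self):
        lab = rgb_to_lab(_single_pixel_tile(255, 255, 255))
        assert lab.L[0, 0] == pytest.approx(100.0, abs=0.01)
        assert lab.a[0, 0] == pytest.approx(0.0, abs=0.01)
        assert lab.b[0, 0] == pytest.approx(0.0, abs=0.01)

    def test_blue_yellow_axis(self):
        assert rgb_to_lab(_single_pixel_tile(0, 0, 255)).b[0, 0] < 0
        assert rgb_to_lab(_single_pixel_tile(255, 255, 0)).b[0, 0] == pytest.approx(94, abs=2)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255))
    def test_matches_reference_formulas(self, r, g, b):
        lab = rgb_to_lab(_single_pixel_tile(r, g, b))
        L, a, bb = _reference_lab(r, g, b)
        assert lab.L[0, 0] == pytest.approx(L, abs=0.05)
        assert lab.a[0, 0] == pytest.approx(a, abs=0.05)
        assert lab.b[0, 0] == pytest.approx(bb, abs=0.05)


class TestROI:
    def test_all_white_tile_has_empty_roi(self):
        tile = _single_pixel_tile(255, 255, 255)
        assert roi_mask(rgb_to_hsv(tile)).sum() == 0

    def test_all_brown_tile_is_full_roi(self):
        tile = hsv_tile(30, 0.6, 0.6)
        assert roi_mask(rgb_to_hsv(tile)).all()

    def test_half_white_half_brown_gives_half_fraction(self):
        white = np.full((8, 8, 3), 255, dtype=np.uint8)
        brown = hsv_tile(30, 0.6, 0.6, shape=(8, 8)).pixels
        tile = RGBTile(pixels=np.concatenate([white, brown], axis=1))
        assert roi_fraction(tile) == pytest.approx(0.5)


class TestStainMask:
    def _hsv(self, hue, sat, shape=(10, 10)):
        return HSVImage(hue=np.full(shape, float(hue)),
                        saturation=np.full(shape, float(sat)),
                        value=np.full(shape, 0.6))

    def test_threshold_out_of_range_rejected(self):
        hsv = self._hsv(30, 0.6)
        with pytest.raises(ValueError):
            stain_mask(hsv, np.ones((10, 10), bool), 1.0 + 1e-6)

    def test_inclusive_boundary_at_full_saturation(self):
        hsv = self._hsv(30, 1.0)
        assert stain_mask(hsv, np.ones((10, 10), bool), 1.0).all()

    def test_uniform_in_band_tile_fully_stained(self):
        hsv = self._hsv(30, 0.6)
        assert stain_mask(hsv, np.ones((10, 10), bool), 0.5).all()

    def test_partial_saturation_split(self):
        """Half the ROI at S=0.3, half at S=0.05: t=0.2 selects exactly the strong half."""
        hue = np.full((10, 10), 30.0)
        sat = np.where(np.arange(10)[None, :] < 5, 0.3, 0.05)
        sat = np.broadcast_to(sat, (10, 10))
        hsv = HSVImage(hue=hue, saturation=sat, value=np.full((10, 10), 0.6))
        mask = stain_mask(hsv, np.ones((10, 10), bool), 0.2)
        assert mask.sum() == 50
        assert mask[:, :5].all() and not mask[:, 5:].any()

    def test_hue_wraparound_band(self):
        hsv = self._hsv(355, 0.6)
        roi = np.ones((10, 10), bool)
        assert stain_mask(hsv, roi, 0.1, hue_band=(350, 20)).all()
        assert not stain_mask(hsv, roi, 0.1, hue_band=(10, 50)).any()

    def test_nesting_and_roi_subset_on_random_tiles(self):
        """stain(t2) is a subset of stain(t1) for t2 >= t1, and of the ROI."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            rgb = rng.integers(0, 256, size=(12, 12, 3), dtype=np.uint8)
            hsv = rgb_to_hsv(RGBTile(pixels=rgb))
            roi = roi_mask(hsv)
            prev = None
            for t in np.linspace(0.0, 1.0, 11):
                m = stain_mask(hsv, roi, float(t))
                assert not (m & ~roi).any()
                if prev is not None:
                    assert not (m & ~prev).any()
                prev = m


class TestFilterTiles:
    def test_mixed_roi_fractions_boundary_kept(self):
        """Fractions {0, ~0.39, ~0.95} at threshold 0.40: boundary rule keeps >= only."""
        white = np.full((10, 10, 3), 255, dtype=np.uint8)
        brown = hsv_tile(30, 0.6, 0.6, shape=(10, 10)).pixels

        def mixed(n_brown_cols, tid):
            px = white.copy()
            px[:, :n_brown_cols] = brown[:, :n_brown_cols]
            return RGBTile(pixels=px, id=tid)

        tiles = [RGBTile(pixels=white, id="blank"),
                 mixed(3, "a"),       # 30% ROI
                 mixed(4, "b"),       # exactly 40%
                 mixed(9, "c")]       # 90%
        kept = filter_tiles(tiles, min_roi_frac=0.40)
        assert [t.id for t in kept] == ["b", "c"]

    def test_empty_input(self):
        assert filter_tiles([]) == []


class TestTileValidation:
    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="3 x 3"):
            RGBTile(pixels=np.zeros((2, 2, 3), dtype=np.uint8))

    def test_wrong_channels_rejected(self):
        with pytest.raises(ValueError):
            RGBTile(pixels=np.zeros((4, 4, 4), dtype=np.uint8))

    def test_alpha_dropped_on_read(self, tmp_path):
        from PIL import Image
        rgba = np.zeros((8, 8, 4), dtype=np.uint8)
        rgba[..., 0] = 200
        rgba[..., 3] = 255
        Image.fromarray(rgba, "RGBA").save(tmp_path / "t.png")
        tile = RGBTile.from_file(tmp_path / "t.png")
        assert tile.pixels.shape == (8, 8, 3)
        assert tile.pixels[..., 0].max() == 200
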