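"""Multi-material Floyd–Steinberg dithering and material-stack output."""

import numpy as np
import pytest

import voxelprint as vp
from voxelprint.errors import EmptyRegionError, ParameterError
from voxelprint.material_dither import NO_MATERIAL

from conftest import reference_floyd_steinberg, uniform_rgba


def _stack(slices, palette):
    n = len(slices)
    return vp.MaterialSliceStack(slices=slices, palette=palette,
                                 pitch_x_mm=0.0423, pitch_y_mm=0.0847,
                                 layer_mm=0.027,
                                 z_positions_mm=np.arange(n) * 0.027)


class TestDitherSlice:
    def test_matches_independent_trace_bit_exactly(self, vero_palette, bw_palette):
        """The kernel reproduces a straightforward trace of the recurrence."""
        rng = np.random.default_rng(23)
        for palette in (bw_palette, vero_palette):
            for shape in ((4, 4), (7, 13), (16, 9)):
                img = rng.uniform(0, 1, shape + (4,))
                img[:, :, 3] = (rng.random(shape) > 0.2).astype(float)
                got = vp.dither_slice(img, palette)
                want = reference_floyd_steinberg(img[:, :, :3], img[:, :, 3],
                                                 palette.linear_rgb)
                np.testing.assert_array_equal(got, want)

    def test_two_pixel_gray_hand_trace(self, bw_palette):
        """Hand-computed: 0.5 gray ties to black (lowest index), the diffused
        +0.5·7/16 error pushes the next pixel to white."""
        img = uniform_rgba((1, 2), [0.5, 0.5, 0.5])
        out = vp.dither_slice(img, bw_palette)
        np.testing.assert_array_equal(out, [[0, 1]])  # (black, white)

    def test_exact_palette_colors_are_fixed_points(self, vero_palette):
        lin = vero_palette.linear_rgb
        img = np.empty((10, 12, 4))
        img[:, :6, :3] = lin[4]   # cyan half
        img[:, 6:, :3] = lin[2]   # black half
        img[:, :, 3] = 1.0
        out = vp.dither_slice(img, vero_palette)
        assert np.all(out[:, :6] == 4) and np.all(out[:, 6:] == 2)

    def test_uniform_gray_dithers_to_half_white(self, bw_palette):
        img = uniform_rgba((64, 64), [0.5, 0.5, 0.5])
        out = vp.dither_slice(img, bw_palette)
        assert np.mean(out == 1) == pytest.approx(0.5, abs=0.01)

    def test_mask_pixels_keep_sentinel_and_absorb_no_error(self, bw_palette):
        img = uniform_rgba((32, 32), [0.5, 0.5, 0.5])
        hole = np.zeros((32, 32), bool)
        hole[8:24, 8:24] = True
        img[hole, 3] = 0.0
        out = vp.dither_slice(img, bw_palette)
        assert np.all(out[hole] == NO_MATERIAL)
        assert np.all(out[~hole] != NO_MATERIAL)

    def test_deterministic(self, vero_palette):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (40, 40, 4))
        np.testing.assert_array_equal(vp.dither_slice(img, vero_palette),
                                      vp.dither_slice(img, vero_palette))

    def test_rejects_out_of_range_channels(self, bw_palette):
        img = uniform_rgba((4, 4), [1.5, 0, 0])
        with pytest.raises(ParameterError):
            vp.dither_slice(img, bw_palette)


class TestMaterialFractions:
    def test_pure_region(self, bw_palette):
        s = np.zeros((16, 16), dtype=np.int16)
        stack = _stack([s], bw_palette)
        f = vp.material_fractions(stack, np.ones((16, 16, 1), bool))
        np.testing.assert_allclose(f, [1.0, 0.0])

    def test_two_material_mixture_recovered(self):
        # 30% cyan + 70% white, dithered over a cyan/white palette
        palette = vp.MaterialPalette([
            vp.Material("cyan", (0.0, 1.0, 1.0, 1.0)),
            vp.Material("white", (1.0, 1.0, 1.0, 1.0)),
        ])
        lin = palette.linear_rgb
        target = 0.30 * lin[0] + 0.70 * lin[1]
        img = uniform_rgba((128, 128), target)
        out = vp.dither_slice(img, palette)
        stack = _stack([out], palette)
        f = vp.material_fractions(stack, np.ones((128, 128, 1), bool))
        np.testing.assert_allclose(f, [0.30, 0.70], atol=0.01)

    def test_additive_over_region_partition(self, bw_palette):
        rng = np.random.default_rng(6)
        s = rng.integers(0, 2, (20, 30), dtype=np.int16)
        stack = _stack([s], bw_palette)
        left = np.zeros((20, 30, 1), bool)
        left[:, :15] = True
        right = ~left
        whole = np.ones((20, 30, 1), bool)
        f_l = vp.material_fractions(stack, left)
        f_r = vp.material_fractions(stack, right)
        f = vp.material_fractions(stack, whole)
        n_l, n_r = left.sum(), right.sum()
        np.testing.assert_allclose(f, (f_l * n_l + f_r * n_r) / (n_l + n_r))

    def test_empty_region_signalled(self, bw_palette):
        s = np.full((4, 4), NO_MATERIAL, dtype=np.int16)
        stack = _stack([s], bw_palette)
        with pytest.raises(EmptyRegionError):
            vp.material_fractions(stack, np.ones((4, 4, 1), bool))


class TestPalette:
    def test_size_limits(self):
        one = [vp.Material("a", (0, 0, 0, 1))]
        with pytest.raises(ParameterError):
            vp.MaterialPalette(one)
        seven = [vp.Material(f"m{i}", (i / 10, 0, 0, 1)) for i in range(7)]
        with pytest.raises(ParameterError):
            vp.MaterialPalette(seven)

    def test_duplicate_colors_rejected(self):
        with pytest.raises(ParameterError):
            vp.MaterialPalette([vp.Material("a", (0, 0, 0, 1)),
                                vp.Material("b", (0, 0, 0, 1))])

    def test_config_round_trip(self, vero_palette):
        back = vp.MaterialPalette.from_config(vero_palette.to_config())
        np.testing.assert_allclose(back.srgb, vero_palette.srgb)
        assert back.names == vero_palette.names


class TestMaterialStackIO:
    def test_checkerboard_bitmaps_complementary(self, bw_palette, tmp_path):
        s = np.indices((8, 8)).sum(axis=0) % 2
        stack = _stack([s.astype(np.int16)], bw_palette)
        vp.write_material_stack(stack, tmp_path, mode="per_material_bitmaps")
        from PIL import Image
        b0 = np.array(Image.open(tmp_path / "layer_0000_black.png"), dtype=bool)
        b1 = np.array(Image.open(tmp_path / "layer_0000_white.png"), dtype=bool)
        assert not np.any(b0 & b1)
        assert np.all(b0 | b1)  # channels OR-reduce to the material mask

    def test_modes_round_trip_identically(self, vero_palette, tmp_path):
        rng = np.random.default_rng(12)
        slices = []
        for _ in range(3):
            s = rng.integers(0, 6, (10, 14)).astype(np.int16)
            s[rng.random((10, 14)) < 0.25] = NO_MATERIAL
            slices.append(s)
        stack = _stack(slices, vero_palette)
        vp.write_material_stack(stack, tmp_path / "idx", mode="indexed_png")
        vp.write_material_stack(stack, tmp_path / "bits",
                                mode="per_material_bitmaps")
        from_idx = vp.read_material_stack(tmp_path / "idx")
        from_bits = vp.read_material_stack(tmp_path / "bits")
        np.testing.assert_array_equal(from_idx.as_array(), stack.as_array())
        np.testing.assert_array_equal(from_bits.as_array(), stack.as_array())
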