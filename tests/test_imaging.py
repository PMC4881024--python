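"""Imaging: intensity transform, enhancement, rotation, gridding, rendering."""

import numpy as np
import pytest
from scipy import ndimage

from kinorm.imaging import (
    ArtifactSpec,
    GeometryError,
    PhosphorImage,
    TransformSpec,
    TransformStateError,
    auto_rotate,
    enhance,
    fit_grid,
    forward_transform,
    generate_synthetic_image,
    locate_blocks,
    read_tiff,
    reverse_transform,
    write_tiff,
)
from kinorm.layout import ArrayLayout
from kinorm.spots import SpotTable

PITCH = 50.0  # μm per pixel


@pytest.fixture(scope="module")
def one_set_layout():
    return ArrayLayout(n_sets=1, set_rows=8, set_cols=8, block_size=8)


def render(layout, values, **kwargs):
    table = SpotTable(layout, values)
    return generate_synthetic_image(table, **kwargs)


class TestReverseTransform:
    def test_zero_maps_to_zero(self):
        img = PhosphorImage(np.zeros((4, 4)))
        out = reverse_transform(img)
        assert out.transform_state == "reverse_transformed"
        assert np.all(out.pixels == 0)

    def test_full_scale_value(self):
        # 65535^2 / 42752 = 4294836225 / 42752, computed independently
        img = PhosphorImage(np.full((2, 2), 65535.0))
        out = reverse_transform(img)
        np.testing.assert_allclose(out.pixels, 4294836225.0 / 42752.0)
        assert out.pixels[0, 0] == pytest.approx(100459.31, abs=0.01)

    def test_monotone_and_state_error(self):
        raw = np.arange(0, 60000, 997.0).reshape(1, -1)
        out = reverse_transform(PhosphorImage(raw))
        assert np.all(np.diff(out.pixels[0]) > 0)
        with pytest.raises(TransformStateError):
            reverse_transform(out)

    def test_saturation_threshold_reachable_below_16bit(self):
        """The smallest raw value whose transform exceeds the 95000
        saturation level, found by brute-force scan, lies below 65535."""
        tf = TransformSpec().tf
        raws = np.arange(0, 65536, dtype=float)
        above = raws[raws ** 2 / tf > 95000]
        assert above.size > 0
        smallest = above[0]
        assert smallest < 65535
        assert (smallest - 1) ** 2 / tf <= 95000 < smallest ** 2 / tf

    def test_forward_reverse_identity_up_to_quantization(self, rng):
        intensity = rng.uniform(0, 90000, size=(32, 32))
        raw = forward_transform(intensity)
        back = reverse_transform(PhosphorImage(raw)).pixels
        # quantization of raw to integers: dI ~ 2*sqrt(I/TF) * 0.5
        tol = np.sqrt(np.maximum(intensity, 1) / TransformSpec().tf) + 0.5
        assert np.all(np.abs(back - intensity) <= tol)


class TestEnhance:
    def test_constant_image_gives_no_response(self, one_set_layout):
        """A featureless image yields no structure: the response is flat
        and negligible relative to the input scale (the truncated filter
        kernels leave a tiny uniform residual)."""
        img = PhosphorImage(np.full((64, 64), 50.0), PITCH, "reverse_transformed")
        enh = enhance(img, one_set_layout)
        assert enh.pixels.max() - enh.pixels.min() <= 1e-9
        assert np.abs(enh.pixels).max() <= 1e-3 * 50

    def test_spot_maximum_at_center(self, one_set_layout):
        px = np.full((64, 64), 10.0)
        yy, xx = np.mgrid[:64, :64]
        sigma = (125.0 / PITCH) / np.sqrt(2)  # matched to the spot radius
        px += 500 * np.exp(-((xx - 30) ** 2 + (yy - 33) ** 2) / (2 * sigma ** 2))
        enh = enhance(PhosphorImage(px, PITCH, "reverse_transformed"), one_set_layout)
        peak = np.unravel_index(np.argmax(enh.pixels), enh.pixels.shape)
        assert abs(peak[0] - 33) <= 1 and abs(peak[1] - 30) <= 1

    def test_single_pixel_impulse_removed_by_opening(self, one_set_layout):
        px = np.full((64, 64), 10.0)
        px[20, 20] = 10000.0
        enh = enhance(PhosphorImage(px, PITCH, "reverse_transformed"), one_set_layout)
        clean = enhance(PhosphorImage(np.full((64, 64), 10.0), PITCH,
                                      "reverse_transformed"), one_set_layout)
        # the impulse survives neither as a local maximum nor as excess response
        assert enh.pixels[20, 20] <= clean.pixels[20, 20] + 1e-6

    def test_raw_image_rejected(self, one_set_layout):
        with pytest.raises(TransformStateError):
            enhance(PhosphorImage(np.zeros((64, 64)), PITCH, "raw"), one_set_layout)


@pytest.fixture(scope="module")
def aligned_enh():
    lay = ArrayLayout(n_sets=1, set_rows=16, set_cols=16, block_size=8)
    vals = np.random.default_rng(3).normal(10, 1.0, size=(1, 16, 16))
    img, _ = render(lay, vals, seed=2)
    return enhance(reverse_transform(img), lay), lay


class TestAutoRotate:
    def test_aligned_grid_gives_zero_angle(self, aligned_enh):
        _, angle = auto_rotate(aligned_enh[0])
        assert abs(angle) <= 0.1

    def test_recovers_injected_rotation(self, aligned_enh):
        enh, lay = aligned_enh
        rot = ndimage.rotate(enh.pixels, 2.0, reshape=False, order=1)
        _, angle = auto_rotate(type(enh)(rot, enh.pixel_pitch))
        assert angle == pytest.approx(-2.0, abs=0.2)

    def test_out_of_range_rotation_clamps_with_warning(self, aligned_enh):
        enh, lay = aligned_enh
        rot = ndimage.rotate(enh.pixels, 5.0, reshape=False, order=1)
        with pytest.warns(UserWarning, match="bound"):
            _, angle = auto_rotate(type(enh)(rot, enh.pixel_pitch))
        assert angle == -3.0


class TestBlocksAndGrid:
    def test_block_count_default_partitioning(self):
        """A 3-set 32x32 slide divides into 3 x 16 = 48 pin blocks."""
        lay = ArrayLayout()
        pitch_px = lay.spot_pitch / PITCH
        w, h = 32 * pitch_px, 96 * pitch_px
        from kinorm.imaging import EnhancedImage

        enh = EnhancedImage(np.zeros((int(h) + 60, int(w) + 60)), PITCH)
        blocks = locate_blocks(enh, (30, 30, 30 + w, 30 + h), lay)
        assert len(blocks) == 48

    def test_padded_bounds_rescale(self, one_set_layout):
        vals = np.random.default_rng(0).normal(10, 1, size=(1, 8, 8))
        img, info = render(one_set_layout, vals, seed=4)
        enh = enhance(reverse_transform(img), one_set_layout)
        x0, y0, x1, y1 = info["bounds"]
        wide = (x0 - 0.025 * (x1 - x0), y0, x1 + 0.025 * (x1 - x0), y1)
        assert len(locate_blocks(enh, wide, one_set_layout)) == 1

    def test_bad_bounds_raise_geometry_error(self, one_set_layout):
        from kinorm.imaging import EnhancedImage

        enh = EnhancedImage(np.zeros((200, 200)), PITCH)
        x0, y0 = 10, 10
        with pytest.raises(GeometryError):
            locate_blocks(enh, (x0, y0, x0 + 89.6, y0 + 44.8), one_set_layout)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fit_grid_recovers_jittered_centers(self, one_set_layout, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(11, 0.5, size=(1, 8, 8))
        img, info = render(one_set_layout, vals, seed=seed + 10,
                           center_jitter_um=50.0)
        enh = enhance(reverse_transform(img), one_set_layout)
        block = locate_blocks(enh, info["bounds"], one_set_layout)[0]
        nodes = fit_grid(block, one_set_layout, PITCH)
        truth = info["centers_px"][0]
        d_um = np.hypot(*(nodes - truth).transpose(2, 0, 1)) * PITCH
        assert (d_um <= 100).sum() >= 63

    def test_fit_grid_with_half_off_spots(self, one_set_layout):
        rng = np.random.default_rng(6)
        vals = rng.normal(11, 0.5, size=(1, 8, 8))
        vals[0, ::2, ::2] = np.nan
        vals[0, 1::2, 1::2] = np.nan
        img, info = render(one_set_layout, vals, seed=16, center_jitter_um=50.0)
        enh = enhance(reverse_transform(img), one_set_layout)
        nodes = fit_grid(locate_blocks(enh, info["bounds"], one_set_layout)[0],
                         one_set_layout, PITCH)
        on = np.isfinite(vals[0])
        d_um = np.hypot(*(nodes - info["centers_px"][0]).transpose(2, 0, 1)) * PITCH
        assert (d_um[on] <= 100).mean() >= 0.9

    def test_blank_block_falls_back_to_nominal(self, one_set_layout):
        img, info = render(one_set_layout, np.full((1, 8, 8), np.nan), seed=7)
        enh = enhance(reverse_transform(img), one_set_layout)
        with pytest.warns(UserWarning, match="nominal"):
            nodes = fit_grid(locate_blocks(enh, info["bounds"], one_set_layout)[0],
                             one_set_layout, PITCH)
        assert nodes.shape == (8, 8, 2)


class TestSyntheticRenderer:
    def test_deterministic_per_seed(self, one_set_layout):
        vals = np.random.default_rng(1).normal(10, 1, size=(1, 8, 8))
        img1, _ = render(one_set_layout, vals, seed=5)
        img2, _ = render(one_set_layout, vals, seed=5)
        img3, _ = render(one_set_layout, vals, seed=6)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert not np.array_equal(img1.pixels, img3.pixels)

    def test_16bit_and_saturation_bookkeeping(self, one_set_layout):
        vals = np.full((1, 8, 8), 18.0)  # far beyond the 16-bit forward range
        img, info = render(one_set_layout, vals, seed=5)
        assert img.pixels.max() <= 65535
        assert info["n_clipped"] > 0

    def test_tiff_round_trip(self, tmp_path, one_set_layout):
        vals = np.random.default_rng(1).normal(10, 1, size=(1, 8, 8))
        img, _ = render(one_set_layout, vals, seed=5)
        path = tmp_path / "slide.tif"
        write_tiff(img, path)
        back = read_tiff(path)
        assert np.array_equal(back.pixels, img.pixels)
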