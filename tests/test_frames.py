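"""Frame-stack I/O, cropping, and masking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import cardiotrace as ct
from cardiotrace import InvalidArgumentError, InvalidDataError
from cardiotrace.frames import LUMA_WEIGHTS, load_mask, save_frames


class TestFrameStack:
    def test_timestamps(self):
        stack = ct.FrameStack(frames=np.zeros((900, 4, 4)), fps=30.0)
        assert stack.timestamps[0] == 0.0
        assert stack.timestamps[-1] == pytest.approx(29.9667, abs=5e-5)
        assert stack.duration == pytest.approx(30.0)

    def test_single_frame(self):
        stack = ct.FrameStack(frames=np.zeros((1, 4, 4)))
        assert len(stack) == 1

    def test_rejects_empty_or_bad_fps(self):
        with pytest.raises(InvalidDataError):
            ct.FrameStack(frames=np.zeros((0, 4, 4)))
        with pytest.raises(InvalidArgumentError):
            ct.FrameStack(frames=np.zeros((2, 4, 4)), fps=0)


class TestLoadSave:
    def test_tiff_roundtrip_is_lossless(self, rng, tmp_path):
        frames = rng.random((5, 12, 12)).astype(np.float32).astype(np.float64)
        stack = ct.FrameStack(frames=frames, fps=25.0)
        path = tmp_path / "stack.tif"
        save_frames(stack, path)
        back = ct.load_frames(path, fps_override=25.0)
        assert np.array_equal(back.frames, frames)
        assert back.fps == 25.0

    def test_single_page_tiff(self, rng, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "one.tif", rng.random((8, 8)).astype(np.float32))
        stack = ct.load_frames(tmp_path / "one.tif")
        assert len(stack) == 1

    def test_fps_defaults_with_warning(self, rng, tmp_path, caplog):
        stack = ct.FrameStack(frames=rng.random((2, 8, 8)))
        save_frames(stack, tmp_path / "s.tif")
        with caplog.at_level("WARNING"):
            back = ct.load_frames(tmp_path / "s.tif")
        assert back.fps == 30.0
        assert any("fps" in r.message for r in caplog.records)

    def test_missing_file(self, tmp_path):
        with pytest.raises(InvalidDataError):
            ct.load_frames(tmp_path / "nope.tif")

    def test_color_tiff_converted_by_luminance(self, rng, tmp_path):
        import tifffile

        rgb = rng.random((3, 8, 8, 3)).astype(np.float32)
        tifffile.imwrite(tmp_path / "rgb.tif", rgb)
        stack = ct.load_frames(tmp_path / "rgb.tif", fps_override=30)
        expected = rgb.astype(np.float64) @ LUMA_WEIGHTS
        assert np.allclose(stack.frames, expected)

    def test_mask_png_roundtrip(self, tmp_path):
        import imageio.v3 as iio

        raster = np.zeros((10, 10), np.uint8)
        raster[2:7, 3:8] = 255
        iio.imwrite(tmp_path / "mask.png", raster)
        mask = load_mask(tmp_path / "mask.png")
        assert np.array_equal(mask.raster, raster != 0)


class TestCrop:
    def test_identity_full_frame(self, rng):
        frames = rng.random((3, 100, 100))
        stack = ct.FrameStack(frames=frames)
        out = ct.crop_to_square(stack, (0, 0, 100, 100))
        assert np.array_equal(out.frames, frames)

    def test_odd_roi_expands_to_even(self, rng):
        stack = ct.FrameStack(frames=rng.random((2, 80, 80)))
        out = ct.crop_to_square(stack, (10, 10, 33, 33))
        assert out.frame_shape == (34, 34)

    def test_rectangular_roi_centered(self, rng):
        frames = rng.random((2, 120, 120))
        stack = ct.FrameStack(frames=frames)
        top, left, h, w = 40, 50, 20, 40
        out = ct.crop_to_square(stack, (top, left, h, w))
        assert out.frame_shape == (40, 40)
        # the requested rows sit centered inside the square, columns unchanged
        sub = out.frames[:, 10:30, :]
        assert np.array_equal(sub, frames[:, top : top + h, left : left + w])

    def test_roi_outside_frame(self, rng):
        stack = ct.FrameStack(frames=rng.random((2, 50, 50)))
        with pytest.raises(InvalidArgumentError):
            ct.crop_to_square(stack, (40, 40, 20, 20))

    def test_clamps_at_border(self, rng):
        stack = ct.FrameStack(frames=rng.random((2, 60, 60)))
        out = ct.crop_to_square(stack, (0, 0, 10, 40))
        assert out.frame_shape == (40, 40)


class TestMask:
    def test_all_ones_is_identity(self, rng):
        frame = rng.random((8, 8))
        mask = ct.Mask(raster=np.ones((8, 8)))
        assert np.array_equal(ct.apply_mask(frame, mask), frame)

    def test_single_pixel(self, rng):
        frame = rng.random((8, 8)) + 1.0
        raster = np.zeros((8, 8))
        raster[3, 4] = 1
        out = ct.apply_mask(frame, ct.Mask(raster=raster))
        assert np.count_nonzero(out) == 1

    def test_dimension_mismatch(self, rng):
        with pytest.raises(InvalidArgumentError):
            ct.apply_mask(rng.random((8, 8)), ct.Mask(raster=np.ones((6, 6))))

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidDataError):
            ct.Mask(raster=np.zeros((4, 4)))

    @settings(max_examples=25, deadline=None)
    @given(
        hnp.arrays(np.float64, (6, 6), elements=st.floats(-10, 10)),
        hnp.arrays(np.bool_, (6, 6)),
    )
    def test_idempotent_and_energy_monotone(self, frame, raster):
        if not raster.any():
            raster[0, 0] = True
        mask = ct.Mask(raster=raster)
        once = ct.apply_mask(frame, mask)
        assert np.array_equal(ct.apply_mask(once, mask), once)
        assert (once**2).sum() <= (frame**2).sum() + 1e-12

    def test_mask_commutes_with_identity_crop(self, rng):
        frames = rng.random((2, 20, 20))
        stack = ct.FrameStack(frames=frames)
        mask = ct.Mask(raster=rng.random((20, 20)) > 0.5)
        a = ct.crop_to_square(
            ct.FrameStack(frames=ct.apply_mask(frames, mask)), (0, 0, 20, 20)
        ).frames
        b = ct.apply_mask(ct.crop_to_square(stack, (0, 0, 20, 20)).frames, mask)
        assert np.array_equal(a, b)


class TestThresholdMask:
    @staticmethod
    def _disk(center, radius, shape):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return np.hypot(yy - center[0], xx - center[1]) <= radius

    def test_fixed_level_recovers_disk(self):
        img = np.full((40, 40), 10.0)
        disk = self._disk((20, 20), 8, img.shape)
        img[disk] = 200.0
        mask = ct.make_threshold_mask(img, method="fixed", level=100)
        assert np.array_equal(mask.raster, disk)

    def test_largest_component_kept(self):
        img = np.full((60, 60), 10.0)
        big = self._disk((20, 20), 10, img.shape)
        small = self._disk((45, 45), 4, img.shape)
        img[big | small] = 200.0
        mask = ct.make_threshold_mask(img, method="fixed", level=100)
        assert np.array_equal(mask.raster, big)

    def test_constant_image_otsu_fails(self):
        with pytest.raises(InvalidDataError):
            ct.make_threshold_mask(np.full((20, 20), 7.0), method="otsu")

    def test_holes_filled(self):
        img = np.full((40, 40), 10.0)
        ring = self._disk((20, 20), 10, img.shape) & ~self._disk((20, 20), 4, img.shape)
        img[ring] = 200.0
        mask = ct.make_threshold_mask(img, method="fixed", level=100)
        assert np.array_equal(mask.raster, self._disk((20, 20), 10, img.shape))
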