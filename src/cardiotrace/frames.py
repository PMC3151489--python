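"""Loading, cropping and masking of recorded frame stacks.

Recordings arrive either as multi-page TIFF stacks (preferred: lossless,
metadata-stable) or as any video container the installed imageio plugins
can decode.  Frames are converted to grayscale with fixed luminance
weights, cropped to an even square around the cell, and multiplied by a
binary region-of-interest mask that zeroes the background -- the
"mask/zero-pad" preparation the polar transform expects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import InvalidArgumentError, InvalidDataError

__all__ = [
    "FrameStack",
    "Mask",
    "load_frames",
    "save_frames",
    "load_mask",
    "crop_to_square",
    "apply_mask",
    "make_threshold_mask",
]

logger = logging.getLogger(__name__)

DEFAULT_FPS = 30.0
#: ITU-R BT.709 luminance weights for RGB -> gray conversion.
LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class FrameStack:
    """Ordered grayscale frames with a frame rate.

    ``frames`` has shape ``(T, H, W)`` (float64, native intensity units);
    ``timestamps`` are derived as ``k / fps``.
    """

    frames: np.ndarray
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] == 0:
            raise InvalidDataError(
                f"frames must be a non-empty (T, H, W) array, got shape {self.frames.shape}"
            )
        if not self.fps > 0:
            raise InvalidArgumentError(f"fps must be positive, got {self.fps}")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def timestamps(self) -> np.ndarray:
        """Per-frame acquisition time in seconds (``k / fps``)."""
        return np.arange(len(self)) / self.fps

    @property
    def duration(self) -> float:
        """Trace duration in seconds (``T / fps``)."""
        return len(self) / self.fps


@dataclass(frozen=True)
class Mask:
    """Binary region-of-interest raster: 1 = cell, 0 = background."""

    raster: np.ndarray

    def __post_init__(self) -> None:
        raster = np.asarray(self.raster) != 0
        if raster.ndim != 2:
            raise InvalidDataError(f"mask must be 2-D, got shape {raster.shape}")
        if not raster.any():
            raise InvalidDataError("mask contains no foreground pixels")
        object.__setattr__(self, "raster", raster)

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape

    @property
    def foreground_fraction(self) -> float:
        return float(self.raster.mean())


def _to_gray(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames)
    if frames.ndim == 4 and frames.shape[-1] in (3, 4):
        return frames[..., :3].astype(np.float64) @ LUMA_WEIGHTS
    if frames.ndim == 3:
        return frames.astype(np.float64)
    raise InvalidDataError(f"unsupported frame array shape {frames.shape}")


def load_frames(path: str | Path, fps_override: float | None = None) -> FrameStack:
    """Read a recording from a multi-page TIFF or a video container.

    Color frames are collapsed to luminance.  The frame rate is taken from
    container metadata when the decoder reports one, else from
    ``fps_override``, else the acquisition default of 30 fps (logged).
    """
    path = Path(path)
    if not path.exists():
        raise InvalidDataError(f"recording not found: {path}")
    fps = None
    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            with tifffile.TiffFile(path) as tf:
                raw = tf.asarray()
                if raw.ndim == 2:
                    raw = raw[None]
        except Exception as exc:  # corrupt container
            raise InvalidDataError(f"cannot read TIFF stack {path}: {exc}") from exc
    else:
        try:
            import imageio.v3 as iio

            raw = np.asarray(iio.imread(path, index=None))
            try:
                meta = iio.immeta(path)
                fps = meta.get("fps")
            except Exception:
                fps = None
        except InvalidDataError:
            raise
        except Exception as exc:
            raise InvalidDataError(
                f"cannot decode {path}: {exc} (is a decoder plugin installed?)"
            ) from exc
    frames = _to_gray(raw)
    if frames.shape[0] == 0:
        raise InvalidDataError(f"{path} contains zero frames")
    if fps is None:
        fps = fps_override
    if fps is None:
        logger.warning("no frame rate in %s metadata; assuming %g fps", path, DEFAULT_FPS)
        fps = DEFAULT_FPS
    return FrameStack(frames=frames, fps=float(fps))


def save_frames(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as a lossless float32 multi-page TIFF."""
    tifffile.imwrite(Path(path), stack.frames.astype(np.float32))


def load_mask(path: str | Path) -> Mask:
    """Read a mask raster (PNG or TIFF); any nonzero pixel is foreground."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raster = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        raster = np.asarray(iio.imread(path))
    if raster.ndim == 3:
        raster = raster[..., :3].max(axis=-1)
    return Mask(raster=raster != 0)


def _enclosing_even_square(top, left, height, width, frame_h, frame_w):
    """Smallest even square enclosing the roi, centered on it, clamped to the
    frame where possible.  Returns (top, left, side, pad_spec)."""
    side = max(height, width)
    side += side % 2
    # center the square on the roi center
    cy = top + height / 2.0
    cx = left + width / 2.0
    t = int(round(cy - side / 2.0))
    l_ = int(round(cx - side / 2.0))
    # clamp inside the frame when it fits
    t = min(max(t, 0), max(frame_h - side, 0)) if side <= frame_h else t
    l_ = min(max(l_, 0), max(frame_w - side, 0)) if side <= frame_w else l_
    pad_top = max(-t, 0)
    pad_left = max(-l_, 0)
    pad_bottom = max(t + side - frame_h, 0)
    pad_right = max(l_ + side - frame_w, 0)
    return t, l_, side, (pad_top, pad_bottom, pad_left, pad_right)


def crop_to_square(stack: FrameStack, roi: tuple[int, int, int, int]) -> FrameStack:
    """Crop every frame to the smallest even square enclosing ``roi``.

    ``roi`` is ``(top, left, height, width)`` in pixel coordinates and must
    lie inside the frames.  Odd or non-square requests are expanded
    symmetrically; when the expansion would leave the frame it is clamped
    at the borders, and zero-padded only if the frame itself is too small.
    """
    top, left, height, width = (int(v) for v in roi)
    H, W = stack.frame_shape
    if height <= 0 or width <= 0:
        raise InvalidArgumentError(f"roi must have positive size, got {roi}")
    if top < 0 or left < 0 or top + height > H or left + width > W:
        raise InvalidArgumentError(f"roi {roi} lies outside the {H}x{W} frames")
    t, l_, side, (pt, pb, pl, pr) = _enclosing_even_square(top, left, height, width, H, W)
    frames = stack.frames
    if pt or pb or pl or pr:
        frames = np.pad(frames, ((0, 0), (pt, pb), (pl, pr)))
        t += pt
        l_ += pl
    out = frames[:, t : t + side, l_ : l_ + side]
    logger.info("crop_to_square: roi %s -> square side %d at (%d, %d)", roi, side, t - pt, l_ - pl)
    return FrameStack(frames=out.copy(), fps=stack.fps)


def apply_mask(frame: np.ndarray, mask: Mask) -> np.ndarray:
    """Zero every pixel outside the mask (idempotent)."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape[-2:] != mask.shape:
        raise InvalidArgumentError(
            f"frame shape {frame.shape[-2:]} does not match mask shape {mask.shape}"
        )
    return frame * mask.raster


def make_threshold_mask(frame: np.ndarray, method: str = "otsu", level: float | None = None) -> Mask:
    """Convenience mask builder: threshold, keep the largest connected
    component, fill holes.

    A user-drawn mask file should always take precedence over this helper;
    it exists for quick looks at recordings that ship without one.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise InvalidDataError("cannot threshold an empty frame")
    if method == "fixed":
        if level is None:
            raise InvalidArgumentError("fixed thresholding requires a level")
        thr = float(level)
    elif method == "otsu":
        if np.ptp(frame) == 0:
            raise InvalidDataError(
                "constant image has no separable foreground; supply a mask file"
            )
        thr = float(threshold_otsu(frame))
    else:
        raise InvalidArgumentError(f"unknown threshold method {method!r}")
    fg = frame > thr
    if not fg.any():
        raise InvalidDataError(
            "thresholding produced an empty foreground; supply a mask file"
        )
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    return Mask(raster=fg)
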