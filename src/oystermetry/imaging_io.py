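"""Image I/O, resizing, and explicit colour-space conversion.

All rasters are 8-bit H×W×3 arrays with a declared colour space; conversions
are always explicit so downstream hue arithmetic can trust the tag.  Hue uses
the 8-bit half-degree convention (0–179), which keeps the segmentation
epsilon integer-friendly.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage import color as skcolor

__all__ = [
    "ColourSpace",
    "RasterImage",
    "HUE_RANGE",
    "load_image",
    "save_image",
    "resize_quarter",
    "convert",
]

#: Number of representable hue levels (half-degrees), i.e. hue lives in [0, 180).
HUE_RANGE = 180

#: Minimum raster side length the pipeline will operate on.
MIN_SIDE = 8


class ColourSpace(str, enum.Enum):
    RGB = "RGB"
    HSV = "HSV"
    YUV = "YUV"


@dataclass
class RasterImage:
    """An 8-bit three-channel raster with a declared colour space.

    Coordinates are row-major, origin top-left, 0-based, addressed as
    ``pixels[y, x]``.
    """

    pixels: np.ndarray
    colour_space: ColourSpace = ColourSpace.RGB
    source_path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H×W×3 pixel array, got shape {px.shape}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise ValueError(
                f"raster must be at least {MIN_SIDE}×{MIN_SIDE}, got {px.shape[0]}×{px.shape[1]}"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in 0–255")
            px = px.astype(np.uint8)
        self.pixels = px
        self.colour_space = ColourSpace(self.colour_space)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def n_pixels(self) -> int:
        return self.height * self.width


def load_image(path: str | Path) -> RasterImage:
    """Read a PNG or JPEG file into an RGB :class:`RasterImage`.

    Grayscale and paletted images are promoted to three RGB channels.
    Unreadable or truncated files raise :class:`OSError` naming the path.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            rgb = im.convert("RGB")
            pixels = np.asarray(rgb, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    return RasterImage(pixels=pixels, colour_space=ColourSpace.RGB, source_path=str(path))


def save_image(img: RasterImage, path: str | Path) -> None:
    """Write a raster to PNG.  Non-RGB rasters are written channel-as-is."""
    Image.fromarray(img.pixels).save(Path(path), format="PNG")


def resize_quarter(img: RasterImage) -> RasterImage:
    """Downsample both dimensions by four using area averaging.

    Output is floor(H/4) × floor(W/4); trailing rows/columns that do not fill
    a complete 4×4 block are dropped.  Colour space is preserved.
    """
    h, w = img.height, img.width
    if h < 32 or w < 32:
        raise ValueError(f"image {h}×{w} too small to quarter (need ≥ 32×32)")
    nh, nw = h // 4, w // 4
    block = img.pixels[: nh * 4, : nw * 4].astype(np.float64)
    block = block.reshape(nh, 4, nw, 4, 3).mean(axis=(1, 3))
    out = np.clip(np.rint(block), 0, 255).astype(np.uint8)
    return RasterImage(out, img.colour_space, img.source_path)


# BT.601 full-range YUV (luma + offset chroma), the common 8-bit convention.
_RGB2YUV = np.array(
    [[0.299, 0.587, 0.114], [-0.14713, -0.28886, 0.436], [0.615, -0.51499, -0.10001]]
)
_YUV_SCALE = np.array([1.0, 0.5 / 0.436, 0.5 / 0.615])  # map U,V into ±0.5


def _rgb_to_hsv(pixels: np.ndarray) -> np.ndarray:
    hsv = skcolor.rgb2hsv(pixels.astype(np.float64) / 255.0)
    out = np.empty_like(hsv)
    out[..., 0] = np.rint(hsv[..., 0] * HUE_RANGE) % HUE_RANGE
    out[..., 1] = np.rint(hsv[..., 1] * 255.0)
    out[..., 2] = np.rint(hsv[..., 2] * 255.0)
    return out.astype(np.uint8)


def _hsv_to_rgb(pixels: np.ndarray) -> np.ndarray:
    hsv = np.empty(pixels.shape, dtype=np.float64)
    hsv[..., 0] = pixels[..., 0] / HUE_RANGE
    hsv[..., 1] = pixels[..., 1] / 255.0
    hsv[..., 2] = pixels[..., 2] / 255.0
    rgb = skcolor.hsv2rgb(hsv)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def _rgb_to_yuv(pixels: np.ndarray) -> np.ndarray:
    rgb = pixels.astype(np.float64)
    yuv = rgb @ _RGB2YUV.T
    yuv *= _YUV_SCALE
    yuv[..., 1] += 128.0
    yuv[..., 2] += 128.0
    return np.clip(np.rint(yuv), 0, 255).astype(np.uint8)


def _yuv_to_rgb(pixels: np.ndarray) -> np.ndarray:
    yuv = pixels.astype(np.float64)
    yuv = yuv - np.array([0.0, 128.0, 128.0])
    yuv /= _YUV_SCALE
    rgb = yuv @ np.linalg.inv(_RGB2YUV).T
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def convert(img: RasterImage, target: ColourSpace | str) -> RasterImage:
    """Convert between RGB, HSV and YUV at 8-bit precision.

    Hue is stored on the 0–179 half-degree scale.  Converting to the current
    colour space is a no-op that emits a warning.  HSV↔YUV goes through RGB.
    """
    target = ColourSpace(target)
    if img.colour_space == target:
        warnings.warn(f"image already in {target.value}; conversion is a no-op", stacklevel=2)
        return RasterImage(img.pixels.copy(), img.colour_space, img.source_path)

    px = img.pixels
    if img.colour_space is ColourSpace.HSV:
        px = _hsv_to_rgb(px)
    elif img.colour_space is ColourSpace.YUV:
        px = _yuv_to_rgb(px)
    # px is now RGB
    if target is ColourSpace.HSV:
        px = _rgb_to_hsv(px)
    elif target is ColourSpace.YUV:
        px = _rgb_to_yuv(px)
    return RasterImage(px, target, img.source_path)
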