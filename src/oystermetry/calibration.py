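"""Reference-object scale calibration and group measurement.

A circular reference object of known physical diameter (a soda cap) is
located with the circle Hough transform on the luma channel of the YUV
image; its pixel radius fixes the millimetre-per-pixel scale.  Group
dimensions are then the sides of the axis-aligned bounding box, converted
to millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import feature as skfeature
from skimage import measure as skmeasure
from skimage.transform import hough_circle

from .imaging_io import ColourSpace, RasterImage
from .segmentation import PixelGroup

__all__ = [
    "CapNotFoundError",
    "DetectedCircle",
    "ScaleCalibration",
    "detect_cap",
    "make_calibration",
    "measure_group",
]


class CapNotFoundError(RuntimeError):
    """No circular reference object detected above the accumulator threshold."""


@dataclass(frozen=True)
class DetectedCircle:
    centre: tuple[float, float]  # (y, x)
    radius_px: float
    accumulator: float


@dataclass(frozen=True)
class ScaleCalibration:
    centre: tuple[float, float]
    radius_px: float
    known_diameter_mm: float

    def __post_init__(self) -> None:
        if self.radius_px <= 0 or self.known_diameter_mm <= 0:
            raise ValueError("radius and known diameter must be positive")

    @property
    def mm_per_px(self) -> float:
        return self.known_diameter_mm / (2.0 * self.radius_px)


def detect_cap(
    img: RasterImage,
    radius_range: tuple[int, int],
    accumulator_threshold: float = 0.35,
    canny_sigma: float = 2.0,
) -> DetectedCircle:
    """Find the reference circle on the luma channel of a YUV image.

    Runs Canny edge detection on Y, then the circle Hough transform over
    integer radii in ``radius_range`` (inclusive).  The circle with the
    highest normalised accumulator wins; ties resolve to the smallest
    (radius, y, x) in scan order, so detection is deterministic.
    """
    if img.colour_space is not ColourSpace.YUV:
        raise ValueError("detect_cap requires a YUV image")
    rmin, rmax = radius_range
    if rmin < 1 or rmax < rmin:
        raise ValueError(f"invalid radius range {radius_range}")
    if rmax >= min(img.height, img.width) // 2 + 1:
        raise ValueError("radius range exceeds image bounds")

    luma = img.pixels[..., 0].astype(np.float64) / 255.0
    edges = skfeature.canny(luma, sigma=canny_sigma)
    radii = np.arange(rmin, rmax + 1)
    acc = hough_circle(edges, radii)
    flat = int(np.argmax(acc))  # first maximum in (radius, y, x) scan order
    ri, cy, cx = np.unravel_index(flat, acc.shape)
    best = float(acc[ri, cy, cx])
    if best < accumulator_threshold:
        raise CapNotFoundError(
            f"no circular reference found in radius range {radius_range} "
            f"(best accumulator {best:.2f} < threshold {accumulator_threshold}); "
            "check that the cap is fully visible and the radius range matches its size"
        )
    return DetectedCircle(centre=(float(cy), float(cx)), radius_px=float(radii[ri]), accumulator=best)


def make_calibration(circle: DetectedCircle, known_diameter_mm: float) -> ScaleCalibration:
    """Bind a detected circle to its known physical diameter."""
    return ScaleCalibration(
        centre=circle.centre,
        radius_px=circle.radius_px,
        known_diameter_mm=known_diameter_mm,
    )


def measure_group(
    group: PixelGroup, cal: ScaleCalibration
) -> tuple[float, float, np.ndarray]:
    """Physical length and width of a group from its bounding box.

    Length is the longer bounding-box side in millimetres, width the
    shorter.  The contour of the binarised group mask (longest closed
    iso-contour) is returned for annotation output.
    """
    if group.n_pixels == 0:
        raise ValueError("cannot measure an empty group")
    p1y, p1x, p2y, p2x = group.bbox
    h_px = p2y - p1y + 1
    w_px = p2x - p1x + 1
    length_mm = max(h_px, w_px) * cal.mm_per_px
    width_mm = min(h_px, w_px) * cal.mm_per_px

    # Contour on a padded local mask so boundary pixels close properly.
    local = np.zeros((h_px + 2, w_px + 2), dtype=np.float64)
    local[group.pixels[:, 0] - p1y + 1, group.pixels[:, 1] - p1x + 1] = 1.0
    contours = skmeasure.find_contours(local, 0.5)
    contour = max(contours, key=len) + np.array([p1y - 1, p1x - 1])
    return length_mm, width_mm, contour
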