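"""Reference-circle detection, mm-per-pixel calibration, and group measurement."""

import numpy as np
import pytest

from oystermetry.calibration import (
    CapNotFoundError,
    DetectedCircle,
    ScaleCalibration,
    detect_cap,
    make_calibration,
    measure_group,
)
from oystermetry.imaging_io import ColourSpace, RasterImage, convert
from oystermetry.segmentation import PixelGroup
from oystermetry.synthetic import SceneSpec, clean_spec, generate_scene


def yuv_with_circles(circles, shape=(200, 200), bg=60, fg=220):
    """Plain background with filled bright circles, converted to YUV."""
    img = np.full((*shape, 3), bg, dtype=np.uint8)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    for cy, cx, r in circles:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = fg
    return convert(RasterImage(img, ColourSpace.RGB), ColourSpace.YUV)


class TestDetectCap:
    def test_synthetic_scene_cap_within_two_px(self):
        spec = clean_spec(SceneSpec(seed=11))
        img, truth = generate_scene(spec)
        yuv = convert(img, ColourSpace.YUV)
        circle = detect_cap(yuv, (21, 39))
        assert circle.radius_px == pytest.approx(truth.cap_radius_px, abs=2)
        ty, tx = truth.cap_centre_px()
        assert circle.centre[0] == pytest.approx(ty, abs=2)
        assert circle.centre[1] == pytest.approx(tx, abs=2)

    def test_no_circle_raises_actionable_error(self):
        yuv = yuv_with_circles([])
        with pytest.raises(CapNotFoundError, match="radius range"):
            detect_cap(yuv, (30, 60))

    def test_radius_range_selects_the_larger_circle(self):
        yuv = yuv_with_circles([(60, 60, 40), (150, 150, 15)])
        circle = detect_cap(yuv, (30, 60))
        assert circle.radius_px == pytest.approx(40, abs=2)
        assert circle.centre == pytest.approx((60, 60), abs=2)

    def test_deterministic(self):
        yuv = yuv_with_circles([(100, 90, 35)])
        c1 = detect_cap(yuv, (25, 45))
        c2 = detect_cap(yuv, (25, 45))
        assert c1 == c2

    def test_requires_yuv(self):
        rgb = RasterImage(np.full((50, 50, 3), 100, np.uint8))
        with pytest.raises(ValueError, match="YUV"):
            detect_cap(rgb, (5, 10))


class TestMakeCalibration:
    @pytest.mark.parametrize(
        "radius,diameter,expected", [(50, 30, 0.30), (15, 30, 1.0), (30, 30, 0.5)]
    )
    def test_mm_per_px_definition(self, radius, diameter, expected):
        circle = DetectedCircle(centre=(0, 0), radius_px=radius, accumulator=1.0)
        cal = make_calibration(circle, diameter)
        assert cal.mm_per_px == pytest.approx(expected)

    def test_doubling_radius_halves_scale(self):
        c1 = DetectedCircle((0, 0), 20, 1.0)
        c2 = DetectedCircle((0, 0), 40, 1.0)
        assert make_calibration(c1, 30).mm_per_px == pytest.approx(
            2 * make_calibration(c2, 30).mm_per_px
        )

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_calibration(DetectedCircle((0, 0), 0.0, 1.0), 30)
        with pytest.raises(ValueError):
            make_calibration(DetectedCircle((0, 0), 10.0, 1.0), -1)


def rect_group(y0, x0, y1, x1):
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    return PixelGroup(
        id=0, pixels=np.column_stack([ys.ravel(), xs.ravel()]), bbox=(y0, x0, y1, x1)
    )


class TestMeasureGroup:
    def test_bbox_definition(self):
        cal = ScaleCalibration((0, 0), radius_px=30, known_diameter_mm=30)  # 0.5 mm/px
        g = rect_group(0, 0, 119, 59)  # 120 x 60 px
        length, width, _ = measure_group(g, cal)
        assert length == pytest.approx(60.0)
        assert width == pytest.approx(30.0)

    def test_square_bbox_length_equals_width(self):
        cal = ScaleCalibration((0, 0), 15, 30)
        length, width, _ = measure_group(rect_group(5, 5, 24, 24), cal)
        assert length == width == pytest.approx(20.0)

    def test_length_always_at_least_width(self):
        cal = ScaleCalibration((0, 0), 10, 25)
        for y1, x1 in [(9, 49), (49, 9), (19, 19)]:
            length, width, _ = measure_group(rect_group(0, 0, y1, x1), cal)
            assert length >= width

    def test_contour_encloses_the_group(self):
        cal = ScaleCalibration((0, 0), 15, 30)
        g = rect_group(10, 20, 19, 44)
        _, _, contour = measure_group(g, cal)
        assert contour[:, 0].min() >= 9 and contour[:, 0].max() <= 20
        assert contour[:, 1].min() >= 19 and contour[:, 1].max() <= 45

    def test_synthetic_ellipse_axes_recovered(self):
        """Measured dimensions match analytic bbox extents within 2 px."""
        spec = clean_spec(SceneSpec(seed=21))
        img, truth = generate_scene(spec)
        from oystermetry.imaging_io import convert
        from oystermetry.segmentation import (
            compute_epsilon,
            discard_background,
            extract_groups,
            modified_dbscan,
        )

        hsv = convert(img, ColourSpace.HSV)
        groups = discard_background(
            extract_groups(modified_dbscan(hsv, compute_epsilon(hsv))), img.n_pixels
        )
        cal = ScaleCalibration(truth.cap_centre_px(), truth.cap_radius_px, truth.cap_diameter_mm)
        tol = 2 * truth.mm_per_px
        matched = 0
        for g in groups:
            cy, cx = g.pixels.mean(axis=0)
            dists = [
                (truth.blob_centre_px(i)[0] - cy) ** 2 + (truth.blob_centre_px(i)[1] - cx) ** 2
                for i in range(len(truth.blobs))
            ]
            i = int(np.argmin(dists))
            if dists[i] > (10 / truth.mm_per_px) ** 2:
                continue  # the cap group
            length, width, _ = measure_group(g, cal)
            true_len, true_wid = truth.blobs[i].extents_mm()
            assert length == pytest.approx(true_len, abs=tol)
            assert width == pytest.approx(true_wid, abs=tol)
            matched += 1
        assert matched == len(truth.blobs)

    def test_empty_group_rejected(self):
        cal = ScaleCalibration((0, 0), 15, 30)
        g = PixelGroup(id=0, pixels=np.empty((0, 2), int), bbox=(0, 0, 0, 0))
        with pytest.raises(ValueError):
            measure_group(g, cal)
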