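"""End-to-end pipeline: segment, calibrate, filter, measure, refine, report.

Stage order follows the measurement workflow: (optional ÷4 resize) → HSV →
hue-adaptive density clustering → background discard → reference-cap
detection on the YUV image and geometric exclusion of its group → MLP group
filter → bounding-box measurement in millimetres → Random Forest refinement
with fused-group splitting → per-image report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ann_filter import AnnModel, filter_groups, train_ann
from .calibration import DetectedCircle, ScaleCalibration, detect_cap, make_calibration, measure_group
from .features import ann_features, rf_features
from .imaging_io import ColourSpace, RasterImage, convert, resize_quarter
from .rf_refine import DEFAULT_RF_SEED, OysterMeasurement, RfModel, refine, train_rf
from .report_stats import ImageReport, summarize
from .segmentation import (
    EpsilonPolicy,
    PixelGroup,
    compute_epsilon,
    discard_background,
    extract_groups,
    modified_dbscan,
)
from .synthetic import SceneSpec, generate_training_sets

__all__ = ["PipelineConfig", "PipelineResult", "process_image", "train_models"]


@dataclass
class PipelineConfig:
    """Tunable pipeline parameters.

    ``reference_diameter_mm`` has no default: the physical size of the
    reference object must be stated explicitly.
    """

    reference_diameter_mm: float
    hough_radius_range: tuple[int, int]
    epsilon_policy: EpsilonPolicy = field(default_factory=EpsilonPolicy)
    min_neighbors: int = 8
    edge_margin: int = 1
    resize: bool = False  # quarter the image before segmentation
    accumulator_threshold: float = 0.35
    cap_overlap_threshold: float = 0.5  # group fraction inside the cap circle

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        policy = EpsilonPolicy(**raw.pop("epsilon_policy", {}))
        raw["hough_radius_range"] = tuple(raw["hough_radius_range"])
        return cls(epsilon_policy=policy, **raw)


@dataclass
class PipelineResult:
    report: ImageReport
    measurements: list[OysterMeasurement]
    cap: DetectedCircle
    calibration: ScaleCalibration
    epsilon: float
    groups: list[PixelGroup]  # post-background-discard, pre-filtering
    kept: list[tuple[PixelGroup, int]]
    removed: list[PixelGroup]


def _cap_overlap(group: PixelGroup, cap: DetectedCircle) -> float:
    cy, cx = cap.centre
    d2 = (group.pixels[:, 0] - cy) ** 2 + (group.pixels[:, 1] - cx) ** 2
    return float((d2 <= cap.radius_px**2).mean())


def process_image(
    img: RasterImage,
    ann_model: AnnModel,
    rf_model: RfModel,
    config: PipelineConfig,
    image_id: str = "image",
) -> PipelineResult:
    """Run the full counting-and-measurement pipeline on one RGB image."""
    if img.colour_space is not ColourSpace.RGB:
        raise ValueError("process_image expects an RGB image")
    if config.resize:
        img = resize_quarter(img)

    hsv = convert(img, ColourSpace.HSV)
    epsilon = compute_epsilon(hsv, config.epsilon_policy)
    label_map = modified_dbscan(hsv, epsilon, config.min_neighbors, config.edge_margin)
    groups = discard_background(extract_groups(label_map), img.n_pixels)

    # The reference object is found on the pre-filter image and its group is
    # excluded from oyster statistics.
    yuv = convert(img, ColourSpace.YUV)
    cap = detect_cap(yuv, config.hough_radius_range, config.accumulator_threshold)
    cal = make_calibration(cap, config.reference_diameter_mm)
    groups = [g for g in groups if _cap_overlap(g, cap) < config.cap_overlap_threshold]

    records = [ann_features(g, groups, img.n_pixels) for g in groups]
    kept, removed = filter_groups(ann_model, groups, records)

    measured = []
    for group, _ann_cls in kept:
        length_mm, width_mm, _ = measure_group(group, cal)
        rec = rf_features(group, length_mm, width_mm, img.height, img.width, cal.mm_per_px)
        measured.append((group, length_mm, width_mm, rec))
    measurements = refine(rf_model, measured)

    report = summarize(measurements, image_id)
    return PipelineResult(
        report=report,
        measurements=measurements,
        cap=cap,
        calibration=cal,
        epsilon=epsilon,
        groups=groups,
        kept=kept,
        removed=removed,
    )


def train_models(
    specs: list[SceneSpec],
    ann_seed: int = 0,
    rf_seed: int = DEFAULT_RF_SEED,
    policy: EpsilonPolicy = EpsilonPolicy(),
) -> tuple[AnnModel, RfModel]:
    """Train both classifiers on auto-labelled synthetic scenes."""
    ann_records, rf_records = generate_training_sets(specs, policy=policy)
    return train_ann(ann_records, seed=ann_seed), train_rf(rf_records, seed=rf_seed)
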