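"""Per-group feature vectors for the two blob classifiers.

Two schemas are produced per segmented pixel group:

* the size-share features used by the MLP filter — each group's pixel share
  of the image, the spread of those shares across the image's groups, and
  its share of all grouped pixels;
* the geometry features used by the Random Forest — length, width and the
  bounding-box corners, scaled by half the image's larger dimension and
  multiplied by 1000 so images of different resolutions are comparable.

Class vocabulary for both: 0 = shadow/noise/reference object, 1 = single
oyster, 2 = fused (two overlapping oysters, or an oyster overlapping noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import PixelGroup

__all__ = [
    "GroupRecordANN",
    "GroupRecordRF",
    "ann_features",
    "rf_features",
    "ann_feature_table",
    "rf_feature_table",
    "ANN_COLUMNS",
    "RF_COLUMNS",
]

ANN_COLUMNS = ["no", "mean", "std", "pixels", "class"]
RF_COLUMNS = ["no", "large", "width", "p1x", "p1y", "p2x", "p2y", "class"]


@dataclass
class GroupRecordANN:
    pct_mean: float  # group pixels / image pixels
    pct_std: float  # population std of pct_mean across the image's groups
    pct_pixels: float  # group pixels / total grouped pixels
    label: int | None = None

    def as_vector(self) -> np.ndarray:
        return np.array([self.pct_mean, self.pct_std, self.pct_pixels])


@dataclass
class GroupRecordRF:
    pct_large: float
    pct_width: float
    pct_p1x: float
    pct_p1y: float
    pct_p2x: float
    pct_p2y: float
    label: int | None = None

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.pct_large, self.pct_width, self.pct_p1x, self.pct_p1y, self.pct_p2x, self.pct_p2y]
        )


def ann_features(
    group: PixelGroup, all_groups: list[PixelGroup], image_pixels: int
) -> GroupRecordANN:
    """Size-share features for one group in the context of its image.

    ``pct_std`` is the population standard deviation of the per-group image
    shares, so every group of the same image carries the same value; a lone
    group gets 0.
    """
    if image_pixels <= 0:
        raise ValueError("image_pixels must be positive")
    shares = np.array([g.n_pixels for g in all_groups], dtype=np.float64) / image_pixels
    total_grouped = sum(g.n_pixels for g in all_groups)
    return GroupRecordANN(
        pct_mean=group.n_pixels / image_pixels,
        pct_std=float(shares.std()) if len(all_groups) > 1 else 0.0,
        pct_pixels=group.n_pixels / total_grouped,
    )


def rf_features(
    group: PixelGroup,
    length_mm: float,
    width_mm: float,
    image_h: int,
    image_w: int,
    mm_per_px: float = 1.0,
) -> GroupRecordRF:
    """Geometry features: dimensions and corners scaled to image size.

    All quantities are divided by half the larger image dimension and
    multiplied by 1000.  Physical lengths are first converted back to pixels
    through ``mm_per_px`` so the denominator shares their unit.
    """
    if image_h <= 0 or image_w <= 0:
        raise ValueError("image dimensions must be positive")
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    if not length_mm >= width_mm >= 0:
        raise ValueError("need length_mm >= width_mm >= 0")
    half = max(image_h, image_w) / 2.0
    scale = 1000.0 / half
    p1y, p1x, p2y, p2x = group.bbox
    return GroupRecordRF(
        pct_large=length_mm / mm_per_px * scale,
        pct_width=width_mm / mm_per_px * scale,
        pct_p1x=p1x * scale,
        pct_p1y=p1y * scale,
        pct_p2x=p2x * scale,
        pct_p2y=p2y * scale,
    )


def ann_feature_table(records: list[GroupRecordANN]) -> pd.DataFrame:
    rows = [
        {
            "no": i + 1,
            "mean": r.pct_mean,
            "std": r.pct_std,
            "pixels": r.pct_pixels,
            "class": r.label,
        }
        for i, r in enumerate(records)
    ]
    return pd.DataFrame(rows, columns=ANN_COLUMNS)


def rf_feature_table(records: list[GroupRecordRF]) -> pd.DataFrame:
    rows = [
        {
            "no": i + 1,
            "large": r.pct_large,
            "width": r.pct_width,
            "p1x": r.pct_p1x,
            "p1y": r.pct_p1y,
            "p2x": r.pct_p2x,
            "p2y": r.pct_p2y,
            "class": r.label,
        }
        for i, r in enumerate(records)
    ]
    return pd.DataFrame(rows, columns=RF_COLUMNS)


def records_from_ann_table(df: pd.DataFrame) -> list[GroupRecordANN]:
    return [
        GroupRecordANN(
            pct_mean=row["mean"],
            pct_std=row["std"],
            pct_pixels=row["pixels"],
            label=None if pd.isna(row["class"]) else int(row["class"]),
        )
        for _, row in df.iterrows()
    ]


def records_from_rf_table(df: pd.DataFrame) -> list[GroupRecordRF]:
    return [
        GroupRecordRF(
            pct_large=row["large"],
            pct_width=row["width"],
            pct_p1x=row["p1x"],
            pct_p1y=row["p1y"],
            pct_p2x=row["p2x"],
            pct_p2y=row["p2y"],
            label=None if pd.isna(row["class"]) else int(row["class"]),
        )
        for _, row in df.iterrows()
    ]
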