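"""Per-image summaries and the paired Wilcoxon signed-rank comparison.

The Wilcoxon test here follows the convention of classical statistical
packages: zero differences are dropped as ties, tied absolute differences
receive mid-ranks, and the reported Z is computed from the smaller of the
two rank sums, so it is always ≤ 0 and its magnitude carries the evidence.
A signed variant (positive-rank-sum based) is also exposed for symmetry
properties.  The normal approximation uses the tie-corrected variance and
no continuity correction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .rf_refine import OysterMeasurement

__all__ = ["ImageReport", "WilcoxonResult", "summarize", "wilcoxon_paired", "write_reports_csv"]


@dataclass
class ImageReport:
    image_id: str
    oyster_count: int
    mean_length_mm: float | None
    mean_width_mm: float | None
    sd_length_mm: float | None
    sd_width_mm: float | None
    degenerate_sd: bool  # single measurement: sd reported as 0 by convention
    measurements: list[OysterMeasurement] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "image": self.image_id,
            "count": self.oyster_count,
            "mean_length_mm": self.mean_length_mm,
            "mean_width_mm": self.mean_width_mm,
            "sd_length_mm": self.sd_length_mm,
            "sd_width_mm": self.sd_width_mm,
            "oysters": [
                {
                    "group_id": m.group_id,
                    "length_mm": m.length_mm,
                    "width_mm": m.width_mm,
                    "class": m.final_class,
                }
                for m in self.measurements
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class WilcoxonResult:
    n_negative: int
    n_positive: int
    n_ties: int
    sum_negative_ranks: float
    sum_positive_ranks: float
    mean_negative_rank: float
    mean_positive_rank: float
    z: float  # min-rank-sum convention, always <= 0; nan if all ties
    z_signed: float  # (T+ - mean)/sd: positive when a tends above b
    p_two_tailed: float
    all_ties: bool = False


def summarize(measurements: list[OysterMeasurement], image_id: str) -> ImageReport:
    """Count and mean/sd of length and width for one image.

    Sample (n−1) standard deviation; a single measurement reports sd 0 with
    the degenerate flag set; an empty list reports missing means.
    """
    n = len(measurements)
    if n == 0:
        return ImageReport(image_id, 0, None, None, None, None, False, [])
    lengths = np.array([m.length_mm for m in measurements])
    widths = np.array([m.width_mm for m in measurements])
    degenerate = n == 1
    sd_l = 0.0 if degenerate else float(lengths.std(ddof=1))
    sd_w = 0.0 if degenerate else float(widths.std(ddof=1))
    return ImageReport(
        image_id=image_id,
        oyster_count=n,
        mean_length_mm=float(lengths.mean()),
        mean_width_mm=float(widths.mean()),
        sd_length_mm=sd_l,
        sd_width_mm=sd_w,
        degenerate_sd=degenerate,
        measurements=list(measurements),
    )


def wilcoxon_paired(a, b) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on differences a − b.

    Negative ranks are pairs with a < b.  Zero differences are dropped;
    |differences| are mid-ranked; the normal approximation applies the
    tie correction Σ(t³−t)/48 and no continuity correction.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-d samples with at least 2 pairs")
    d = a - b
    ties_zero = int((d == 0).sum())
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0, 0, ties_zero, 0.0, 0.0, 0.0, 0.0, math.nan, math.nan, math.nan, True)

    ranks = sps.rankdata(np.abs(d))
    pos = d > 0
    t_pos = float(ranks[pos].sum())
    t_neg = float(ranks[~pos].sum())
    n_pos = int(pos.sum())
    n_neg = n - n_pos

    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_corr = float((counts.astype(np.float64) ** 3 - counts).sum()) / 48.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr)
    if sigma == 0:
        z = z_signed = math.nan
        p = math.nan
    else:
        z = (min(t_pos, t_neg) - mu) / sigma
        z_signed = (t_pos - mu) / sigma
        p = 2.0 * sps.norm.sf(abs(z_signed))
    return WilcoxonResult(
        n_negative=n_neg,
        n_positive=n_pos,
        n_ties=ties_zero,
        sum_negative_ranks=t_neg,
        sum_positive_ranks=t_pos,
        mean_negative_rank=t_neg / n_neg if n_neg else 0.0,
        mean_positive_rank=t_pos / n_pos if n_pos else 0.0,
        z=z,
        z_signed=z_signed,
        p_two_tailed=p,
    )


def write_reports_csv(reports: list[ImageReport], path: str | Path) -> None:
    """Batch CSV across images, one row per image."""
    rows = [
        {
            "image": r.image_id,
            "count": r.oyster_count,
            "mean_length_mm": r.mean_length_mm,
            "mean_width_mm": r.mean_width_mm,
            "sd_length_mm": r.sd_length_mm,
            "sd_width_mm": r.sd_width_mm,
        }
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)
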