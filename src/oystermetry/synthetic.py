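"""Ground-truthed synthetic oyster scenes.

Emulates the study's field photographs: a uniform blue background with hue
jitter, elliptical oyster-coloured blobs with internal hue texture, optional
offset shadows (drawn beneath their oyster so only a crescent is visible),
small noise specks, and one circular reference cap of known pixel radius and
declared physical diameter.  Every blob's centre, axes, and axis-aligned
extents are recorded in millimetres and pixels.

All geometric randomness is drawn in resolution-independent units (positions
as image fractions, sizes in millimetres), so re-rendering the same seed at
double resolution produces the geometrically identical scene — the property
the scale-equivariance checks rely on.  Per-pixel texture noise comes from a
separate stream and does not perturb geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import ScaleCalibration, measure_group
from .features import GroupRecordANN, GroupRecordRF, ann_features, rf_features
from .imaging_io import HUE_RANGE, ColourSpace, RasterImage, convert
from .segmentation import (
    EpsilonPolicy,
    PixelGroup,
    compute_epsilon,
    discard_background,
    extract_groups,
    modified_dbscan,
)

__all__ = [
    "SceneSpec",
    "BlobTruth",
    "SceneTruth",
    "generate_scene",
    "generate_training_sets",
    "label_group",
    "clean_spec",
    "scaled_spec",
]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene; defaults are the study conditions."""

    image_size: tuple[int, int] = (360, 360)  # (H, W) px
    cap_radius_px: float = 30.0
    cap_diameter_mm: float = 30.0  # a standard soda cap
    background_hue: float = 120.0  # blue, 0-179 scale
    background_sat: float = 200.0
    background_val: float = 140.0
    hue_jitter_sd: float = 1.2
    n_oysters: int = 6
    major_axis_mm: tuple[float, float] = (25.0, 45.0)
    minor_axis_mm: tuple[float, float] = (14.0, 24.0)
    oyster_hue_band: tuple[float, float] = (12.0, 24.0)  # tan/brown
    oyster_sat: float = 150.0
    oyster_val: float = 180.0
    texture_hue_sd: float = 1.5
    shadow_prob: float = 0.35
    shadow_offset_mm: tuple[float, float] = (4.0, 4.0)  # (dy, dx)
    shadow_hue: float = 138.0
    shadow_sat: float = 180.0
    shadow_val: float = 60.0
    n_noise_specks: int = 4
    speck_radius_mm: tuple[float, float] = (1.5, 3.0)
    speck_hue_range: tuple[float, float] = (40.0, 90.0)
    fused_prob: float = 0.15
    seed: int = 0

    @property
    def mm_per_px(self) -> float:
        return self.cap_diameter_mm / (2.0 * self.cap_radius_px)


def clean_spec(spec: SceneSpec, **overrides) -> SceneSpec:
    """A copy of ``spec`` with shadows, fused pairs, and specks disabled."""
    return replace(spec, shadow_prob=0.0, fused_prob=0.0, n_noise_specks=0, **overrides)


def scaled_spec(spec: SceneSpec, factor: int) -> SceneSpec:
    """Re-render the same physical scene at ``factor``× pixel resolution."""
    h, w = spec.image_size
    return replace(
        spec, image_size=(h * factor, w * factor), cap_radius_px=spec.cap_radius_px * factor
    )


@dataclass
class BlobTruth:
    centre_mm: tuple[float, float]  # (y, x)
    major_mm: float
    minor_mm: float
    theta: float  # major-axis angle from +x, radians
    is_fused: bool = False
    fused_partner: int | None = None  # index into SceneTruth.blobs
    base_hue: float = 0.0

    def extents_mm(self) -> tuple[float, float]:
        """Axis-aligned bounding extents (length, width) before rasterization."""
        a, b = self.major_mm / 2.0, self.minor_mm / 2.0
        ext_x = 2.0 * math.hypot(a * math.cos(self.theta), b * math.sin(self.theta))
        ext_y = 2.0 * math.hypot(a * math.sin(self.theta), b * math.cos(self.theta))
        return max(ext_x, ext_y), min(ext_x, ext_y)


@dataclass
class SceneTruth:
    blobs: list[BlobTruth]
    shadows: list[tuple[int, tuple[float, float]]]  # (blob index, centre_mm)
    specks: list[tuple[tuple[float, float], float]]  # (centre_mm, radius_mm)
    cap_centre_mm: tuple[float, float]
    cap_radius_px: float
    cap_diameter_mm: float
    mm_per_px: float
    seed: int

    def cap_centre_px(self) -> tuple[float, float]:
        return (
            self.cap_centre_mm[0] / self.mm_per_px,
            self.cap_centre_mm[1] / self.mm_per_px,
        )

    def blob_centre_px(self, i: int) -> tuple[float, float]:
        cy, cx = self.blobs[i].centre_mm
        return cy / self.mm_per_px, cx / self.mm_per_px


_EDGE_PAD_MM = 3.0
_GAP_MM = 2.0
_MAX_ATTEMPTS = 1000


def _sample_centre(rng, h_mm, w_mm, clearance):
    if h_mm - 2 * clearance <= 0 or w_mm - 2 * clearance <= 0:
        raise ValueError("scene too small for the requested object sizes")
    u, v = rng.random(), rng.random()
    return (
        clearance + u * (h_mm - 2 * clearance),
        clearance + v * (w_mm - 2 * clearance),
    )


def _collides(centre, radius, placed):
    return any(
        math.hypot(centre[0] - c[0], centre[1] - c[1]) < radius + r + _GAP_MM
        for c, r in placed
    )


def _sample_axes(rng, spec: SceneSpec) -> tuple[float, float]:
    major = rng.uniform(*spec.major_axis_mm)
    minor = rng.uniform(*spec.minor_axis_mm)
    minor = min(minor, 0.85 * major)
    return major, minor


def _place_geometry(spec: SceneSpec) -> SceneTruth:
    rng = np.random.default_rng([spec.seed, 0])
    h, w = spec.image_size
    mmpp = spec.mm_per_px
    h_mm, w_mm = h * mmpp, w * mmpp

    placed: list[tuple[tuple[float, float], float]] = []  # (centre_mm, bounding radius)

    cap_r_mm = spec.cap_diameter_mm / 2.0
    cap_centre = _sample_centre(rng, h_mm, w_mm, cap_r_mm + _EDGE_PAD_MM)
    placed.append((cap_centre, cap_r_mm))

    blobs: list[BlobTruth] = []
    while len(blobs) < spec.n_oysters:
        fused = (
            spec.fused_prob > 0
            and spec.n_oysters - len(blobs) >= 2
            and rng.random() < spec.fused_prob
        )
        if fused:
            maj1, min1 = _sample_axes(rng, spec)
            maj2, min2 = _sample_axes(rng, spec)
            theta = rng.uniform(0.0, math.pi)
            # near-tangent overlap: separation is 85% of the sum of semi-majors
            d = 0.85 * (maj1 + maj2) / 2.0
            half_span = (maj1 + maj2) / 4.0 + d / 2.0
            for attempt in range(_MAX_ATTEMPTS):
                mid = _sample_centre(rng, h_mm, w_mm, half_span + _EDGE_PAD_MM)
                c1 = (mid[0] - d / 2.0 * math.sin(theta), mid[1] - d / 2.0 * math.cos(theta))
                c2 = (mid[0] + d / 2.0 * math.sin(theta), mid[1] + d / 2.0 * math.cos(theta))
                # collision per member circle, so a pair is not boxed into one
                # oversized disc
                if not _collides(c1, maj1 / 2.0, placed) and not _collides(
                    c2, maj2 / 2.0, placed
                ):
                    break
            else:
                raise ValueError(
                    "could not place all oysters without overlap; "
                    "reduce n_oysters or enlarge the image"
                )
            placed.append((c1, maj1 / 2.0))
            placed.append((c2, maj2 / 2.0))
            i = len(blobs)
            blobs.append(
                BlobTruth(c1, maj1, min1, theta, is_fused=True, fused_partner=i + 1)
            )
            blobs.append(
                BlobTruth(c2, maj2, min2, theta, is_fused=True, fused_partner=i)
            )
        else:
            major, minor = _sample_axes(rng, spec)
            theta = rng.uniform(0.0, math.pi)
            for attempt in range(_MAX_ATTEMPTS):
                c = _sample_centre(rng, h_mm, w_mm, major / 2.0 + _EDGE_PAD_MM)
                if not _collides(c, major / 2.0, placed):
                    break
            else:
                raise ValueError(
                    "could not place all oysters without overlap; "
                    "reduce n_oysters or enlarge the image"
                )
            placed.append((c, major / 2.0))
            blobs.append(BlobTruth(c, major, minor, theta))

    shadows: list[tuple[int, tuple[float, float]]] = []
    dy, dx = spec.shadow_offset_mm
    for i, blob in enumerate(blobs):
        if rng.random() < spec.shadow_prob:
            shadows.append((i, (blob.centre_mm[0] + dy, blob.centre_mm[1] + dx)))

    specks: list[tuple[tuple[float, float], float]] = []
    for _ in range(spec.n_noise_specks):
        r = rng.uniform(*spec.speck_radius_mm)
        for attempt in range(_MAX_ATTEMPTS):
            c = _sample_centre(rng, h_mm, w_mm, r + _EDGE_PAD_MM)
            if not _collides(c, r, placed):
                break
        else:
            raise ValueError("could not place noise specks; enlarge the image")
        placed.append((c, r))
        specks.append((c, r))

    return SceneTruth(
        blobs=blobs,
        shadows=shadows,
        specks=specks,
        cap_centre_mm=cap_centre,
        cap_radius_px=spec.cap_radius_px,
        cap_diameter_mm=spec.cap_diameter_mm,
        mm_per_px=mmpp,
        seed=spec.seed,
    )


def _ellipse_mask(shape, centre_px, a_px, b_px, theta):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    y = yy - centre_px[0]
    x = xx - centre_px[1]
    ct, st = math.cos(theta), math.sin(theta)
    xr = x * ct + y * st
    yr = -x * st + y * ct
    return (xr / a_px) ** 2 + (yr / b_px) ** 2 <= 1.0


def _circle_mask(shape, centre_px, r_px):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - centre_px[0]) ** 2 + (xx - centre_px[1]) ** 2 <= r_px**2


def generate_scene(spec: SceneSpec) -> tuple[RasterImage, SceneTruth]:
    """Render one scene; deterministic (byte-identical) for a fixed seed."""
    truth = _place_geometry(spec)
    rng = np.random.default_rng([spec.seed, 1])
    h, w = spec.image_size
    mmpp = spec.mm_per_px

    hue = np.full((h, w), spec.background_hue) + rng.normal(0.0, spec.hue_jitter_sd, (h, w))
    sat = np.full((h, w), spec.background_sat)
    val = np.full((h, w), spec.background_val)

    def to_px(c_mm):
        return (c_mm[0] / mmpp, c_mm[1] / mmpp)

    for i, centre in truth.shadows:
        blob = truth.blobs[i]
        m = _ellipse_mask(
            (h, w), to_px(centre), blob.major_mm / 2 / mmpp, blob.minor_mm / 2 / mmpp, blob.theta
        )
        hue[m] = spec.shadow_hue + rng.normal(0.0, 0.8, int(m.sum()))
        sat[m] = spec.shadow_sat
        val[m] = spec.shadow_val

    for centre, r in truth.specks:
        m = _circle_mask((h, w), to_px(centre), r / mmpp)
        base = rng.uniform(*spec.speck_hue_range)
        hue[m] = base + rng.normal(0.0, 0.8, int(m.sum()))
        sat[m] = 150.0
        val[m] = 150.0

    for i, blob in enumerate(truth.blobs):
        m = _ellipse_mask(
            (h, w),
            to_px(blob.centre_mm),
            blob.major_mm / 2 / mmpp,
            blob.minor_mm / 2 / mmpp,
            blob.theta,
        )
        if blob.fused_partner is not None and blob.fused_partner < i:
            # stuck oysters share shell coloration, so the fused union stays
            # hue-connected and segments as a single group
            blob.base_hue = truth.blobs[blob.fused_partner].base_hue + float(
                rng.normal(0.0, 1.0)
            )
        else:
            blob.base_hue = float(rng.uniform(*spec.oyster_hue_band))
        hue[m] = blob.base_hue + rng.normal(0.0, spec.texture_hue_sd, int(m.sum()))
        sat[m] = spec.oyster_sat
        val[m] = spec.oyster_val

    cap_m = _circle_mask((h, w), to_px(truth.cap_centre_mm), spec.cap_radius_px)
    hue[cap_m] = 160.0
    sat[cap_m] = 120.0
    val[cap_m] = 220.0

    hsv = np.stack(
        [
            np.rint(hue) % HUE_RANGE,
            np.clip(np.rint(sat), 0, 255),
            np.clip(np.rint(val), 0, 255),
        ],
        axis=-1,
    ).astype(np.uint8)
    img = convert(RasterImage(hsv, ColourSpace.HSV), ColourSpace.RGB)
    return img, truth


def _blob_fractions(group: PixelGroup, truth: SceneTruth) -> np.ndarray:
    """Fraction of the group's pixels inside each truth blob's ellipse."""
    ys = group.pixels[:, 0].astype(np.float64)
    xs = group.pixels[:, 1].astype(np.float64)
    fracs = np.empty(len(truth.blobs))
    for i, blob in enumerate(truth.blobs):
        cy, cx = truth.blob_centre_px(i)
        a = blob.major_mm / 2 / truth.mm_per_px
        b = blob.minor_mm / 2 / truth.mm_per_px
        ct, st = math.cos(blob.theta), math.sin(blob.theta)
        xr = (xs - cx) * ct + (ys - cy) * st
        yr = -(xs - cx) * st + (ys - cy) * ct
        fracs[i] = float(((xr / a) ** 2 + (yr / b) ** 2 <= 1.0).mean())
    return fracs


def label_group(group: PixelGroup, truth: SceneTruth, overlap_threshold: float = 0.7) -> int:
    """Ground-truth class of a segmented group by overlap with the truth.

    A group at least ``overlap_threshold`` inside one blob is an oyster (1);
    a group covered to that level by a fused pair, with both members holding
    a substantial share, is a fused group (2); anything else (shadow
    crescents, specks) is noise (0).
    """
    if not truth.blobs:
        return 0
    fracs = _blob_fractions(group, truth)
    for i, blob in enumerate(truth.blobs):
        j = blob.fused_partner
        if j is None or j < i:
            continue
        if fracs[i] >= 0.15 and fracs[j] >= 0.15 and fracs[i] + fracs[j] >= overlap_threshold:
            return 2
    if fracs.max() >= overlap_threshold:
        return 1
    return 0


def _cap_fraction(group: PixelGroup, truth: SceneTruth) -> float:
    cy, cx = truth.cap_centre_px()
    d2 = (group.pixels[:, 0] - cy) ** 2 + (group.pixels[:, 1] - cx) ** 2
    return float((d2 <= truth.cap_radius_px**2).mean())


def _shadow_fraction(group: PixelGroup, truth: SceneTruth) -> float:
    best = 0.0
    ys = group.pixels[:, 0].astype(np.float64)
    xs = group.pixels[:, 1].astype(np.float64)
    for i, centre in truth.shadows:
        blob = truth.blobs[i]
        cy, cx = centre[0] / truth.mm_per_px, centre[1] / truth.mm_per_px
        a = blob.major_mm / 2 / truth.mm_per_px
        b = blob.minor_mm / 2 / truth.mm_per_px
        ct, st = math.cos(blob.theta), math.sin(blob.theta)
        xr = (xs - cx) * ct + (ys - cy) * st
        yr = -(xs - cx) * st + (ys - cy) * ct
        best = max(best, float(((xr / a) ** 2 + (yr / b) ** 2 <= 1.0).mean()))
    return best


def generate_training_sets(
    specs: list[SceneSpec],
    policy: EpsilonPolicy = EpsilonPolicy(),
    min_neighbors: int = 8,
    edge_margin: int = 1,
    overlap_threshold: float = 0.7,
) -> tuple[list[GroupRecordANN], list[GroupRecordRF]]:
    """Segment scenes and auto-label their groups from the ground truth.

    The reference-cap group is excluded (the pipeline removes it
    geometrically before classification), and shadow-origin groups are
    excluded from the geometry table only — in deployment the size-based
    filter has already removed shadows before the forest sees anything.
    """
    if not specs:
        raise ValueError("need at least one scene spec")
    ann_records: list[GroupRecordANN] = []
    rf_records: list[GroupRecordRF] = []
    for spec in specs:
        img, truth = generate_scene(spec)
        hsv = convert(img, ColourSpace.HSV)
        eps = compute_epsilon(hsv, policy)
        label_map = modified_dbscan(hsv, eps, min_neighbors, edge_margin)
        groups = extract_groups(label_map)
        groups = discard_background(groups, img.n_pixels)
        groups = [g for g in groups if _cap_fraction(g, truth) < 0.5]
        if not groups:
            continue
        cal = ScaleCalibration(
            centre=truth.cap_centre_px(),
            radius_px=truth.cap_radius_px,
            known_diameter_mm=truth.cap_diameter_mm,
        )
        h, w = spec.image_size
        for g in groups:
            cls = label_group(g, truth, overlap_threshold)
            rec = ann_features(g, groups, img.n_pixels)
            rec.label = cls
            ann_records.append(rec)
            if cls == 0 and _shadow_fraction(g, truth) >= 0.5:
                continue
            length_mm, width_mm, _ = measure_group(g, cal)
            rf = rf_features(g, length_mm, width_mm, h, w, cal.mm_per_px)
            rf.label = cls
            rf_records.append(rf)
    return ann_records, rf_records
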