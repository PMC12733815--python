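"""Benchmark routines on ground-truthed synthetic scenes.

These drive the package's self-validation: paired-vector construction from a
published signed-rank structure, an independent connected-component oracle
for the segmentation, end-to-end count/dimension recovery against generator
truth, scale equivariance, fused-split bookkeeping, and report determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .ann_filter import AnnModel
from .calibration import measure_group
from .imaging_io import ColourSpace, RasterImage, convert
from .pipeline import PipelineConfig, process_image
from .rf_refine import RfModel
from .segmentation import (
    PixelLabelMap,
    compute_epsilon,
    discard_background,
    extract_groups,
    hue_distance,
    modified_dbscan,
)
from .synthetic import SceneSpec, SceneTruth, clean_spec, generate_scene, scaled_spec
from .synthetic import _place_geometry

__all__ = [
    "placeable",
    "usable_seeds",
    "rank_structure_pairs",
    "hue_component_map",
    "segmentation_matches_components",
    "RecoveryResult",
    "evaluate_clean_scenes",
    "scale_equivariance_deviation_mm",
    "fused_split_bookkeeping",
    "default_config",
]

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def default_config(spec: SceneSpec) -> PipelineConfig:
    """Pipeline configuration matching a scene spec's reference cap."""
    r = spec.cap_radius_px
    return PipelineConfig(
        reference_diameter_mm=spec.cap_diameter_mm,
        hough_radius_range=(int(0.7 * r), int(1.3 * r)),
    )


def placeable(spec: SceneSpec) -> bool:
    """Whether the spec's objects can be laid out without overlap."""
    try:
        _place_geometry(spec)
    except ValueError:
        return False
    return True


def usable_seeds(rng: np.random.Generator, n: int, make_spec) -> list[int]:
    """Draw ``n`` seeds whose scenes place successfully.

    Random sequential placement can occasionally jam (a fraction of a percent
    of draws for crowded fused-pair layouts); such seeds are skipped
    deterministically rather than surfacing as generation errors mid-batch.
    """
    out: list[int] = []
    while len(out) < n:
        s = int(rng.integers(0, 2**31 - 1))
        if placeable(make_spec(s)):
            out.append(s)
    return out


def rank_structure_pairs(
    positive_ranks: set[int], n_pairs: int, n_zero_ties: int
) -> tuple[np.ndarray, np.ndarray]:
    """Paired vectors (a, b) realising a given signed-rank structure.

    Ranks 1..n (n = n_pairs − n_zero_ties) with the listed ranks positive and
    the rest negative; each difference magnitude equals its rank, so the
    ranking is unambiguous and free of tied magnitudes.
    """
    n = n_pairs - n_zero_ties
    if not positive_ranks <= set(range(1, n + 1)):
        raise ValueError("positive_ranks must be a subset of 1..n")
    neg = [r for r in range(1, n + 1) if r not in positive_ranks]
    diffs = [0.0] * n_zero_ties + sorted(positive_ranks) + [-r for r in neg]
    return np.array(diffs), np.zeros(n_pairs)


def hue_component_map(
    hsv: RasterImage, background_hue: float, epsilon: float, edge_margin: int = 1
) -> np.ndarray:
    """8-connected components of the epsilon-thresholded hue mask.

    Pixels are split into background-like (circular hue distance to the
    background hue ≤ epsilon) and foreground; each side is labelled
    independently and border-margin pixels are set to −1.  Component ids are
    consecutive and deterministic.
    """
    hue = hsv.pixels[..., 0].astype(np.float64)
    fg = hue_distance(hue, background_hue) > epsilon
    comp = np.full(hue.shape, -1, dtype=np.int32)
    nxt = 0
    for mask in (~fg, fg):
        lab, n = ndimage.label(mask, structure=_EIGHT_CONN)
        comp[mask] = lab[mask] - 1 + nxt
        nxt += n
    comp[:edge_margin], comp[-edge_margin:] = -1, -1
    comp[:, :edge_margin], comp[:, -edge_margin:] = -1, -1
    return comp


def segmentation_matches_components(label_map: PixelLabelMap, comp: np.ndarray) -> bool:
    """Partition agreement between density clusters and hue components.

    On a hue-separable image every cluster must coincide with one component,
    restricted to cluster-assigned pixels: the cluster→component mapping is a
    bijection and each component's assigned pixels form exactly one cluster.
    (Pixels the clustering leaves unassigned — the border band and sub-core
    slivers such as one-pixel ellipse tips — carry no vote.)
    """
    gids = label_map.group_ids
    assigned = gids >= 0
    n_groups = label_map.n_groups
    seen_components = set()
    for gid in range(n_groups):
        comps_here = np.unique(comp[gids == gid])
        if comps_here.size != 1 or comps_here[0] < 0:
            return False
        c = int(comps_here[0])
        if c in seen_components:
            return False
        seen_components.add(c)
        # assigned pixels of this component must be exactly this group
        if not (gids[(comp == c) & assigned] == gid).all():
            return False
    # every component containing assigned pixels must have been claimed
    claimed = np.unique(comp[assigned])
    return set(int(c) for c in claimed) == seen_components


@dataclass
class RecoveryResult:
    n_scenes: int
    n_exact: int
    abs_errors_mm: list[float]
    length_errors_mm: list[float]
    width_errors_mm: list[float]

    @property
    def exact_fraction(self) -> float:
        return self.n_exact / self.n_scenes

    @property
    def mae_mm(self) -> float:
        return float(np.mean(self.abs_errors_mm))


def _match_measurements(result, truth: SceneTruth) -> list[tuple[float, float, float, float]]:
    """Pair each reported measurement with its nearest truth blob's extents."""
    groups = {g.id: g for g, _ in result.kept}
    out = []
    for m in result.measurements:
        g = groups[m.group_id]
        cy, cx = g.pixels.mean(axis=0)
        d2 = [
            (truth.blob_centre_px(i)[0] - cy) ** 2 + (truth.blob_centre_px(i)[1] - cx) ** 2
            for i in range(len(truth.blobs))
        ]
        i = int(np.argmin(d2))
        true_len, true_wid = truth.blobs[i].extents_mm()
        out.append((m.length_mm, m.width_mm, true_len, true_wid))
    return out


def evaluate_clean_scenes(
    ann: AnnModel,
    rf: RfModel,
    seeds: list[int],
    base_spec: SceneSpec = SceneSpec(),
) -> RecoveryResult:
    """Count and dimension recovery on held-out clean scenes."""
    cfg = default_config(base_spec)
    n_exact = 0
    abs_err, len_err, wid_err = [], [], []
    for seed in seeds:
        spec = clean_spec(replace(base_spec, seed=seed))
        img, truth = generate_scene(spec)
        result = process_image(img, ann, rf, cfg, image_id=str(seed))
        if result.report.oyster_count == len(truth.blobs):
            n_exact += 1
        for length, width, true_len, true_wid in _match_measurements(result, truth):
            len_err.append(abs(length - true_len))
            wid_err.append(abs(width - true_wid))
            abs_err += [len_err[-1], wid_err[-1]]
    return RecoveryResult(len(seeds), n_exact, abs_err, len_err, wid_err)


def scale_equivariance_deviation_mm(
    ann: AnnModel, rf: RfModel, seed: int, base_spec: SceneSpec = SceneSpec()
) -> float:
    """Largest mm disagreement between a scene and its 2× re-rendering.

    Compares the calibrated bounding-box measurements of the filtered groups
    (before Random Forest refinement, whose discrete class boundary is not
    part of the measurement chain).
    """
    spec1 = clean_spec(replace(base_spec, seed=seed))
    spec2 = scaled_spec(spec1, 2)
    dims = []
    for spec in (spec1, spec2):
        img, _ = generate_scene(spec)
        result = process_image(img, ann, rf, default_config(spec), image_id="s")
        per_group = []
        for g, _cls in result.kept:
            cy, cx = g.pixels.mean(axis=0) * result.calibration.mm_per_px
            per_group.append((cy, cx, *measure_group(g, result.calibration)[:2]))
        dims.append(per_group)
    if len(dims[0]) != len(dims[1]):
        raise AssertionError("group counts differ between resolutions")
    devs = []
    for cy, cx, l1, w1 in dims[0]:
        # pair with the physically nearest group at the other resolution
        _, l2, w2 = min(
            ((cy - cy2) ** 2 + (cx - cx2) ** 2, l2, w2) for cy2, cx2, l2, w2 in dims[1]
        )
        devs += [abs(l1 - l2), abs(w1 - w2)]
    return max(devs)


def fused_split_bookkeeping(
    ann: AnnModel,
    rf: RfModel,
    seeds: list[int],
    base_spec: SceneSpec = SceneSpec(),
) -> tuple[int, float]:
    """Across fused-heavy scenes: (number of split pairs, worst |sum − fused length|)."""
    cfg = default_config(base_spec)
    n_splits = 0
    worst = 0.0
    for seed in seeds:
        spec = replace(base_spec, seed=seed, fused_prob=0.6, shadow_prob=0.0, n_noise_specks=0)
        img, _ = generate_scene(spec)
        result = process_image(img, ann, rf, cfg, image_id=str(seed))
        groups = {g.id: g for g, _ in result.kept}
        by_source: dict[int, list[float]] = {}
        for m in result.measurements:
            if m.final_class == "2-split":
                by_source.setdefault(m.source_group_id, []).append(m.length_mm)
        for gid, halves in by_source.items():
            assert len(halves) == 2, "a fused group must contribute exactly two records"
            fused_len, _, _ = measure_group(groups[gid], result.calibration)
            worst = max(worst, abs(sum(halves) - fused_len))
            n_splits += 1
    return n_splits, worst
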