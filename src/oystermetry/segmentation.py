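"""Hue-adaptive density clustering of image pixels.

A DBSCAN variant specialised to the pixel grid: every pixel's neighbourhood
is its eight adjacent pixels, the density radius (epsilon) is derived from
the image's mean hue, pixels inside a border margin are excluded, and each
pixel ends up in one of three roles —

* ``2``  core pixel: at least ``min_neighbors`` of its eight neighbours lie
  within hue distance epsilon,
* ``1``  boundary pixel: not core, but adjacent to a core within epsilon,
* ``-1`` outlier or border-margin pixel.

Connected cores (adjacent and within epsilon of each other) plus their
boundary pixels form a group.  Hue distance is circular on the 0–179 scale.
Groups covering more than a tenth of the image are treated as background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .imaging_io import HUE_RANGE, ColourSpace, RasterImage

__all__ = [
    "EpsilonPolicy",
    "PixelLabelMap",
    "PixelGroup",
    "hue_distance",
    "compute_epsilon",
    "modified_dbscan",
    "extract_groups",
    "discard_background",
]

logger = logging.getLogger(__name__)

# Fixed neighbour scan order (dy, dx): row-major over the 3×3 window.
# Boundary pixels adopt the group of the first adjacent core in this order,
# making group assignment independent of visitation order.
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class EpsilonPolicy:
    """Linear hue-to-epsilon policy: eps = clamp(scale_factor * mean_hue)."""

    scale_factor: float = 0.06
    floor: float = 2.0
    cap: float = 30.0

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.floor > self.cap:
            raise ValueError("floor must not exceed cap")


@dataclass
class PixelLabelMap:
    """Per-pixel role labels {-1, 1, 2} and group membership."""

    labels: np.ndarray  # H×W int8
    group_ids: np.ndarray  # H×W int32, -1 = no group

    def __post_init__(self) -> None:
        if self.labels.shape != self.group_ids.shape:
            raise ValueError("labels and group_ids must have identical shape")

    @property
    def n_groups(self) -> int:
        return int(self.group_ids.max()) + 1 if self.group_ids.size else 0


@dataclass
class PixelGroup:
    """One connected cluster of pixels with its tight bounding box.

    ``bbox`` is (p1Y, p1X, p2Y, p2X): inclusive upper-left and lower-right
    corners in pixel coordinates.
    """

    id: int
    pixels: np.ndarray  # (n, 2) array of (y, x)
    bbox: tuple[int, int, int, int]

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def p1(self) -> tuple[int, int]:
        return self.bbox[0], self.bbox[1]

    @property
    def p2(self) -> tuple[int, int]:
        return self.bbox[2], self.bbox[3]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


def hue_distance(a, b, hue_range: int = HUE_RANGE):
    """Circular distance on the hue wheel: min(|Δh|, range − |Δh|)."""
    d = np.abs(np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64))
    return np.minimum(d, hue_range - d)


def compute_epsilon(img: RasterImage, policy: EpsilonPolicy = EpsilonPolicy()) -> float:
    """Epsilon from the image's mean hue, clamped to the policy band."""
    if img.colour_space is not ColourSpace.HSV:
        raise ValueError("compute_epsilon requires an HSV image")
    mean_hue = float(img.pixels[..., 0].mean())
    eps = policy.scale_factor * mean_hue
    clamped = min(max(eps, policy.floor), policy.cap)
    if clamped != eps:
        logger.warning("epsilon %.3f clamped to %.3f", eps, clamped)
    return clamped


def _neighbor_distances(hue: np.ndarray) -> list[tuple[tuple[int, int], np.ndarray]]:
    """Circular hue distance from each pixel to each of its 8 neighbours.

    Off-image neighbours get infinite distance.
    """
    h, w = hue.shape
    out = []
    for dy, dx in _OFFSETS:
        d = np.full((h, w), np.inf)
        ys = slice(max(0, -dy), h - max(0, dy))
        xs = slice(max(0, -dx), w - max(0, dx))
        ysn = slice(max(0, dy), h - max(0, -dy))
        xsn = slice(max(0, dx), w - max(0, -dx))
        d[ys, xs] = hue_distance(hue[ys, xs], hue[ysn, xsn])
        out.append(((dy, dx), d))
    return out


def modified_dbscan(
    img: RasterImage,
    epsilon: float,
    min_neighbors: int = 8,
    edge_margin: int = 1,
) -> PixelLabelMap:
    """Label every pixel as core (2), boundary (1), or outlier/edge (-1).

    Parameters
    ----------
    img : HSV raster; only the hue channel enters the distance.
    epsilon : positive hue-distance radius.
    min_neighbors : 1–8, count of within-epsilon neighbours required for a
        core pixel.
    edge_margin : width in pixels of the excluded border band (>= 1).
    """
    if img.colour_space is not ColourSpace.HSV:
        raise ValueError("modified_dbscan requires an HSV image")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if not 1 <= min_neighbors <= 8:
        raise ValueError("min_neighbors must be in 1..8")
    if edge_margin < 1:
        raise ValueError("edge_margin must be >= 1")

    hue = img.pixels[..., 0].astype(np.float64)
    h, w = hue.shape

    interior = np.zeros((h, w), dtype=bool)
    interior[edge_margin : h - edge_margin, edge_margin : w - edge_margin] = True

    dists = _neighbor_distances(hue)
    within = [(off, d <= epsilon) for off, d in dists]
    n_close = np.zeros((h, w), dtype=np.int8)
    for _, m in within:
        n_close += m
    core = (n_close >= min_neighbors) & interior

    # Connect adjacent cores whose hue distance is within epsilon.  Forward
    # offsets suffice for an undirected graph.
    idx = np.full((h, w), -1, dtype=np.int64)
    core_yx = np.nonzero(core)
    n_core = core_yx[0].size
    idx[core_yx] = np.arange(n_core)

    rows, cols = [], []
    for (dy, dx), m in within:
        if (dy, dx) not in ((0, 1), (1, -1), (1, 0), (1, 1)):
            continue
        sy, sx = np.nonzero(core & m)
        ny, nx = sy + dy, sx + dx
        ok = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
        sy, sx, ny, nx = sy[ok], sx[ok], ny[ok], nx[ok]
        ok = core[ny, nx]
        rows.append(idx[sy[ok], sx[ok]])
        cols.append(idx[ny[ok], nx[ok]])

    group_ids = np.full((h, w), -1, dtype=np.int32)
    if n_core:
        if rows:
            r = np.concatenate(rows)
            c = np.concatenate(cols)
        else:
            r = c = np.empty(0, dtype=np.int64)
        graph = coo_matrix((np.ones(r.size), (r, c)), shape=(n_core, n_core))
        _, comp = connected_components(graph, directed=False)
        # Renumber components by raster order of their first core pixel so ids
        # are deterministic and independent of library internals.
        order = np.full(comp.max() + 1, -1, dtype=np.int32)
        nxt = 0
        for ci in comp:  # cores are already in raster order
            if order[ci] < 0:
                order[ci] = nxt
                nxt += 1
        group_ids[core_yx] = order[comp]

    labels = np.full((h, w), -1, dtype=np.int8)
    labels[core] = 2

    # Boundary pixels: non-core interior pixels within epsilon of an adjacent
    # core; first qualifying neighbour in fixed scan order wins.
    candidate = interior & ~core
    for (dy, dx), m in within:
        take = candidate & m & (group_ids < 0)
        ty, tx = np.nonzero(take)
        ny, nx = ty + dy, tx + dx
        ok = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
        ty, tx, ny, nx = ty[ok], tx[ok], ny[ok], nx[ok]
        ok = core[ny, nx]
        ty, tx, ny, nx = ty[ok], tx[ok], ny[ok], nx[ok]
        group_ids[ty, tx] = group_ids[ny, nx]
        labels[ty, tx] = 1

    return PixelLabelMap(labels=labels, group_ids=group_ids)


def extract_groups(label_map: PixelLabelMap) -> list[PixelGroup]:
    """Collect per-group pixel lists and tight bounding boxes.

    Groups are returned sorted by descending pixel count (ties broken by id).
    """
    gids = label_map.group_ids
    groups: list[PixelGroup] = []
    for gid in range(label_map.n_groups):
        ys, xs = np.nonzero(gids == gid)
        if ys.size == 0:
            continue
        pix = np.column_stack([ys, xs]).astype(np.int32)
        bbox = (int(ys.min()), int(xs.min()), int(ys.max()), int(xs.max()))
        groups.append(PixelGroup(id=gid, pixels=pix, bbox=bbox))
    groups.sort(key=lambda g: (-g.n_pixels, g.id))
    return groups


def discard_background(groups: list[PixelGroup], total_pixels: int) -> list[PixelGroup]:
    """Drop any group holding more than a tenth of the image's pixels.

    Such groups are, by assumption, the uniform background.  A group of
    exactly total/10 pixels is kept (the rule is strictly "more than").
    """
    kept = []
    for g in groups:
        if g.n_pixels > total_pixels / 10:
            logger.info("discarding background group %d (%d px)", g.id, g.n_pixels)
        else:
            kept.append(g)
    return kept
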