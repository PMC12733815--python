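"""Density-clustering segmentation: hand examples, a naive pure-Python
oracle, and the partition/monotonicity invariants."""

import numpy as np
import pytest

from oystermetry.imaging_io import ColourSpace, RasterImage
from oystermetry.segmentation import (
    EpsilonPolicy,
    compute_epsilon,
    discard_background,
    extract_groups,
    hue_distance,
    modified_dbscan,
)

OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def hsv_image(hue: np.ndarray) -> RasterImage:
    h, w = hue.shape
    px = np.stack([hue, np.full((h, w), 200), np.full((h, w), 150)], axis=-1).astype(np.uint8)
    return RasterImage(px, ColourSpace.HSV)


def naive_dbscan(hue, epsilon, min_neighbors=8, edge_margin=1):
    """Independent reimplementation with explicit loops and BFS grouping."""

    def dist(a, b):
        d = abs(float(a) - float(b))
        return min(d, 180 - d)

    h, w = hue.shape
    interior = lambda y, x: edge_margin <= y < h - edge_margin and edge_margin <= x < w - edge_margin
    in_img = lambda y, x: 0 <= y < h and 0 <= x < w

    core = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            if not interior(y, x):
                continue
            n = sum(
                1
                for dy, dx in OFFSETS
                if in_img(y + dy, x + dx) and dist(hue[y, x], hue[y + dy, x + dx]) <= epsilon
            )
            core[y, x] = n >= min_neighbors

    group = np.full((h, w), -1, dtype=int)
    next_id = 0
    for y in range(h):
        for x in range(w):
            if core[y, x] and group[y, x] < 0:
                stack = [(y, x)]
                group[y, x] = next_id
                while stack:
                    cy, cx = stack.pop()
                    for dy, dx in OFFSETS:
                        ny, nx = cy + dy, cx + dx
                        if (
                            in_img(ny, nx)
                            and core[ny, nx]
                            and group[ny, nx] < 0
                            and dist(hue[cy, cx], hue[ny, nx]) <= epsilon
                        ):
                            group[ny, nx] = next_id
                            stack.append((ny, nx))
                next_id += 1

    labels = np.full((h, w), -1, dtype=int)
    labels[core] = 2
    for y in range(h):
        for x in range(w):
            if not interior(y, x) or core[y, x]:
                continue
            for dy, dx in OFFSETS:
                ny, nx = y + dy, x + dx
                if in_img(ny, nx) and core[ny, nx] and dist(hue[y, x], hue[ny, nx]) <= epsilon:
                    labels[y, x] = 1
                    group[y, x] = group[ny, nx]
                    break
    return labels, group


class TestComputeEpsilon:
    def test_mean_of_constant_hue(self):
        img = hsv_image(np.full((10, 10), 120))
        assert compute_epsilon(img, EpsilonPolicy(0.1, 2, 30)) == pytest.approx(12.0)

    def test_floor_clamp_on_zero_hue(self):
        img = hsv_image(np.zeros((10, 10)))
        assert compute_epsilon(img, EpsilonPolicy(0.1, 2, 30)) == 2.0

    def test_arithmetic_mean_of_two_bands(self):
        hue = np.full((10, 10), 60)
        hue[5:] = 120
        assert compute_epsilon(hsv_image(hue), EpsilonPolicy(0.1, 2, 30)) == pytest.approx(9.0)

    def test_requires_hsv(self):
        img = RasterImage(np.zeros((10, 10, 3), np.uint8), ColourSpace.RGB)
        with pytest.raises(ValueError):
            compute_epsilon(img)


class TestHueDistance:
    def test_circular_wraparound(self):
        assert hue_distance(5, 175) == 10
        assert hue_distance(0, 90) == 90
        assert hue_distance(120, 120) == 0


class TestModifiedDbscan:
    def test_two_band_image_yields_two_groups(self):
        """Blue background with a foreground block: one group each."""
        hue = np.full((20, 20), 120)
        hue[7:13, 7:13] = 15
        lm = modified_dbscan(hsv_image(hue), epsilon=10, min_neighbors=8, edge_margin=1)
        assert lm.n_groups == 2
        groups = extract_groups(lm)
        fg = min(groups, key=lambda g: g.n_pixels)
        assert fg.n_pixels == 36  # full 6x6 block: ring pixels join as boundary
        assert fg.bbox == (7, 7, 12, 12)

    def test_uniform_image_single_group_of_non_edge_pixels(self):
        lm = modified_dbscan(hsv_image(np.full((16, 16), 90)), epsilon=5)
        assert lm.n_groups == 1
        assert (lm.group_ids[1:-1, 1:-1] == 0).all()
        assert (lm.labels[0, :] == -1).all() and (lm.labels[:, 0] == -1).all()

    def test_checkerboard_all_outliers(self):
        hue = np.indices((12, 12)).sum(axis=0) % 2 * 90
        lm = modified_dbscan(hsv_image(hue), epsilon=1)
        assert (lm.labels == -1).all()
        assert lm.n_groups == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("epsilon,min_neighbors", [(10, 8), (25, 5), (60, 8)])
    def test_matches_naive_oracle_on_random_images(self, seed, epsilon, min_neighbors):
        """Exact agreement with a loop-based reimplementation of the rules."""
        rng = np.random.default_rng(seed)
        # blocky hue field with noise: realistic mix of plateaus and outliers
        hue = rng.integers(0, 180, (6, 6)).repeat(4, axis=0).repeat(4, axis=1)
        hue = (hue + rng.integers(-3, 4, hue.shape)) % 180
        lm = modified_dbscan(hsv_image(hue), epsilon, min_neighbors)
        labels, groups = naive_dbscan(hue.astype(float), epsilon, min_neighbors)
        np.testing.assert_array_equal(lm.labels, labels)
        # partitions must agree exactly (ids are both raster-ordered)
        np.testing.assert_array_equal(lm.group_ids, groups)

    def test_label_conservation(self):
        rng = np.random.default_rng(5)
        hue = rng.integers(0, 180, (24, 24))
        lm = modified_dbscan(hsv_image(hue), epsilon=20)
        counts = {v: int((lm.labels == v).sum()) for v in (-1, 1, 2)}
        assert sum(counts.values()) == 24 * 24
        # outliers and only outliers lack a group
        assert ((lm.labels == -1) == (lm.group_ids == -1)).all()

    def test_every_group_has_a_core_pixel(self):
        rng = np.random.default_rng(6)
        hue = rng.integers(0, 180, (8, 8)).repeat(3, axis=0).repeat(3, axis=1)
        lm = modified_dbscan(hsv_image(hue), epsilon=15)
        for gid in range(lm.n_groups):
            assert (lm.labels[lm.group_ids == gid] == 2).any()

    def test_raising_epsilon_never_adds_outliers(self):
        rng = np.random.default_rng(7)
        hue = rng.integers(0, 180, (20, 20))
        n_out = [
            int((modified_dbscan(hsv_image(hue), eps).labels == -1).sum())
            for eps in (5, 15, 40, 90)
        ]
        assert n_out == sorted(n_out, reverse=True)

    def test_parameter_validation(self):
        img = hsv_image(np.full((10, 10), 50))
        with pytest.raises(ValueError):
            modified_dbscan(img, epsilon=0)
        with pytest.raises(ValueError):
            modified_dbscan(img, epsilon=5, min_neighbors=9)
        with pytest.raises(ValueError):
            modified_dbscan(img, epsilon=5, edge_margin=0)


class TestExtractGroups:
    def test_sorted_by_descending_size_with_tight_bboxes(self):
        hue = np.full((30, 30), 120)
        hue[2:5, 2:5] = 10  # 3x3
        hue[10:20, 10:20] = 40  # 10x10
        hue[24:28, 2:8] = 70  # 4x6
        lm = modified_dbscan(hsv_image(hue), epsilon=10, min_neighbors=3)
        groups = extract_groups(lm)
        sizes = [g.n_pixels for g in groups]
        assert sizes == sorted(sizes, reverse=True)
        for g in groups:
            ys, xs = g.pixels[:, 0], g.pixels[:, 1]
            assert g.bbox == (ys.min(), xs.min(), ys.max(), xs.max())

    def test_empty_map_gives_empty_list(self):
        hue = np.indices((12, 12)).sum(axis=0) % 2 * 90
        lm = modified_dbscan(hsv_image(hue), epsilon=1)
        assert extract_groups(lm) == []


class TestDiscardBackground:
    def _fake_group(self, gid, n):
        from oystermetry.segmentation import PixelGroup

        pix = np.column_stack([np.zeros(n, int), np.arange(n)])
        return PixelGroup(id=gid, pixels=pix, bbox=(0, 0, 0, n - 1))

    def test_over_tenth_discarded(self):
        groups = [self._fake_group(0, 5000), self._fake_group(1, 300), self._fake_group(2, 120)]
        kept = discard_background(groups, 100 * 100)
        assert [g.n_pixels for g in kept] == [300, 120]

    def test_exactly_tenth_kept(self):
        groups = [self._fake_group(0, 1000)]
        assert len(discard_background(groups, 10000)) == 1

    def test_empty_input(self):
        assert discard_background([], 10000) == []
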