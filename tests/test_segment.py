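"""Threshold / area-opening / component-selection / hull semantics.

Independent oracles: an explicit stack-based flood fill for connected
components and a point-in-convex-hull test via half-plane checks.
"""

import numpy as np
import pytest

from ioimap import (convex_hull_mask, remove_small_components,
                    segment_activation, select_largest_components,
                    threshold_activity)


def flood_fill_components(mask, connectivity=8):
    """Oracle: list of pixel-index sets, one per connected component."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                 (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    comps = []
    for r, c in np.argwhere(mask):
        if seen[r, c]:
            continue
        stack, comp = [(r, c)], set()
        seen[r, c] = True
        while stack:
            cr, cc = stack.pop()
            comp.add((cr, cc))
            for dr, dc in neigh:
                nr, nc = cr + dr, cc + dc
                if (0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1]
                        and mask[nr, nc] and not seen[nr, nc]):
                    seen[nr, nc] = True
                    stack.append((nr, nc))
        comps.append(comp)
    return comps


def in_hull_oracle(point, vertices):
    """True if point is inside/on the convex hull of vertices (2-D)."""
    from itertools import combinations
    pts = np.asarray(vertices, dtype=float)
    p = np.asarray(point, dtype=float)
    if len(pts) == 1:
        return np.allclose(p, pts[0])
    # p is in the hull iff it is a convex combination of <= 3 vertices
    for combo in combinations(range(len(pts)), min(3, len(pts))):
        a = np.vstack([pts[list(combo)].T, np.ones(len(combo))])
        b = np.append(p, 1.0)
        coef, residual, *_ = np.linalg.lstsq(a, b, rcond=None)
        if np.all(coef > -1e-9) and np.allclose(a @ coef, b, atol=1e-9):
            return True
    return False


class TestThreshold:
    def test_hand_computed_mean_sd_case(self):
        """Values {0,0,0,0,10}: mean 2, population SD 4, threshold 6."""
        amap = np.zeros((1, 5))
        amap[0, 4] = 10.0
        trep = np.ones((1, 5), bool)
        z, mask = threshold_activity(amap, trep)
        assert z == pytest.approx(6.0)
        assert np.argwhere(mask).tolist() == [[0, 4]]

    def test_constant_map_gives_empty_mask(self):
        z, mask = threshold_activity(np.full((4, 4), 2.5), np.ones((4, 4), bool))
        assert z == pytest.approx(2.5)
        assert not mask.any()

    def test_statistics_use_trepanation_pixels_only(self):
        amap = np.zeros((2, 5))
        amap[0] = [0, 0, 0, 0, 10]
        amap[1] = 1e6  # outside the trepanation, must not matter
        trep = np.zeros((2, 5), bool)
        trep[0] = True
        z, mask = threshold_activity(amap, trep)
        assert z == pytest.approx(6.0)
        assert mask.sum() == 1

    def test_affine_transform_preserves_mask(self):
        rng = np.random.default_rng(5)
        amap = rng.random((16, 16))
        trep = rng.random((16, 16)) < 0.8
        _, base = threshold_activity(amap, trep)
        _, scaled = threshold_activity(3.7 * amap + 11.1, trep)
        assert np.array_equal(base, scaled)

    def test_empty_trepanation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            threshold_activity(np.zeros((4, 4)), np.zeros((4, 4), bool))

    def test_raising_k_sd_shrinks_mask_monotonically(self):
        rng = np.random.default_rng(6)
        amap = rng.random((20, 20))
        trep = np.ones((20, 20), bool)
        _, m1 = threshold_activity(amap, trep, k_sd=0.5)
        _, m2 = threshold_activity(amap, trep, k_sd=1.0)
        _, m3 = threshold_activity(amap, trep, k_sd=2.0)
        assert not np.any(m2 & ~m1)
        assert not np.any(m3 & ~m2)


class TestSmallComponentRemoval:
    def test_nine_pixel_blob_removed_ten_pixel_kept(self):
        nine = np.zeros((10, 10), bool)
        nine[1:4, 1:4] = True
        assert not remove_small_components(nine, min_size=10).any()
        ten = nine.copy()
        ten[4, 1] = True
        assert np.array_equal(remove_small_components(ten, min_size=10), ten)

    def test_diagonal_pixels_connectivity(self):
        mask = np.zeros((5, 5), bool)
        mask[1, 1] = mask[2, 2] = True
        # one 2-px component under 8-connectivity: survives min_size 2
        assert remove_small_components(mask, 2, connectivity=8).sum() == 2
        # two 1-px components under 4-connectivity: both removed
        assert not remove_small_components(mask, 2, connectivity=4).any()

    def test_empty_mask_stays_empty(self):
        assert not remove_small_components(np.zeros((6, 6), bool)).any()

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(9)
        for _ in range(10):
            mask = rng.random((20, 20)) < 0.35
            min_size = int(rng.integers(2, 8))
            got = remove_small_components(mask, min_size, connectivity)
            expected = np.zeros_like(mask)
            for comp in flood_fill_components(mask, connectivity):
                if len(comp) >= min_size:
                    for r, c in comp:
                        expected[r, c] = True
            assert np.array_equal(got, expected)


class TestLargestComponents:
    @staticmethod
    def _blob_mask(sizes, gap=2, width=30):
        """Horizontal 1-px-high runs of the given sizes, well separated."""
        mask = np.zeros((2 * len(sizes) + 2, max(sizes) + 2), bool)
        for i, s in enumerate(sizes):
            mask[1 + 2 * i, 1:1 + s] = True
        return mask

    def test_three_largest_of_four_kept(self):
        mask = self._blob_mask([50, 30, 20, 10])
        union, comps = select_largest_components(mask, k=3)
        assert sorted(n for _, n, _ in comps) == [20, 30, 50]
        assert union.sum() == 100

    def test_fewer_than_k_keeps_all(self):
        mask = self._blob_mask([5, 7])
        union, comps = select_largest_components(mask, k=3)
        assert len(comps) == 2
        assert np.array_equal(union, mask)

    def test_equal_sizes_tie_broken_by_raster_order(self):
        mask = self._blob_mask([20, 20, 20, 20])
        union, comps = select_largest_components(mask, k=3)
        rows = sorted({r for r, _ in np.argwhere(union)})
        assert rows == [1, 3, 5]  # the three earliest in raster order
        assert len(comps) == 3


class TestConvexHull:
    def test_two_pixels_fill_connecting_segment(self):
        mask = np.zeros((3, 8), bool)
        mask[1, 1] = mask[1, 6] = True
        hull = convex_hull_mask(mask)
        assert np.argwhere(hull).tolist() == [[1, c] for c in range(1, 7)]

    def test_filled_rectangle_is_fixed_point(self):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 3:7] = True
        assert np.array_equal(convex_hull_mask(mask), mask)

    def test_empty_mask_gives_empty_hull(self):
        assert not convex_hull_mask(np.zeros((5, 5), bool)).any()

    def test_idempotent_and_superset(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            mask = rng.random((15, 15)) < 0.1
            hull = convex_hull_mask(mask)
            assert not np.any(mask & ~hull)
            assert np.array_equal(convex_hull_mask(hull), hull)

    def test_matches_point_in_hull_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            mask = np.zeros((10, 10), bool)
            pts = rng.integers(0, 10, size=(6, 2))
            mask[pts[:, 0], pts[:, 1]] = True
            hull = convex_hull_mask(mask)
            vertices = np.argwhere(mask)
            for r in range(10):
                for c in range(10):
                    assert hull[r, c] == in_hull_oracle((r, c), vertices), (r, c)


class TestSegmentationChain:
    def test_nesting_chain_on_random_maps(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            amap = rng.random((24, 24))
            rr, cc = np.mgrid[0:24, 0:24]
            trep = (rr - 12) ** 2 + (cc - 12) ** 2 <= 100
            seg = segment_activation(amap, trep, min_size=3)
            assert not np.any(seg.activation & ~seg.opened_map)
            assert not np.any(seg.opened_map & ~seg.thresholded_map)
            assert not np.any(seg.thresholded_map & ~trep)
            assert not np.any(seg.activation & ~seg.hull)
            assert len(seg.components) <= 3

    def test_full_chain_affine_invariant(self):
        rng = np.random.default_rng(15)
        amap = rng.random((20, 20))
        trep = np.ones((20, 20), bool)
        a = segment_activation(amap, trep, min_size=2)
        b = segment_activation(0.4 * amap + 7.0, trep, min_size=2)
        assert b.z_thresh == pytest.approx(0.4 * a.z_thresh + 7.0)
        for attr in ("thresholded_map", "opened_map", "activation", "hull"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))
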