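import numpy as np
import pytest

import mvtrack.boundary as boundary_mod
from mvtrack import (BoundaryNotFoundError, BoxSpec, CandidateRegion,
                     find_enclosed_regions, qualifies, recursive_search,
                     region_centroid)

from _oracles import (enclosed_background_components, random_blob_mask,
                      threshold_scan_oracle)


def region_stub(xmin, xmax, ymin, ymax):
    return CandidateRegion(pixels=np.zeros((1, 2), dtype=int), contour=[],
                           xmin=xmin, xmax=xmax, ymin=ymin, ymax=ymax)


def assert_closed_cycle(contour):
    """Consecutive contour pixels are 8-neighbors; last wraps to first."""
    n = len(contour)
    if n == 1:
        return
    for k in range(n):
        ax, ay = contour[k]
        bx, by = contour[(k + 1) % n]
        assert max(abs(ax - bx), abs(ay - by)) == 1


class TestFindEnclosedRegions:
    def test_minimal_single_pixel_hole(self):
        mask = np.ones((5, 5), dtype=np.uint8)
        mask[2, 2] = 0
        (region,) = find_enclosed_regions(mask)
        assert region.area == 1
        assert (region.xmin, region.xmax, region.ymin, region.ymax) == (2, 2, 2, 2)
        assert region.contour == [(2, 2)]

    def test_square_annulus_hole_and_perimeter_contour(self):
        mask = np.ones((9, 9), dtype=np.uint8)
        mask[2:7, 2:7] = 0
        (region,) = find_enclosed_regions(mask)
        assert region.area == 25
        assert (region.xmax - region.xmin, region.ymax - region.ymin) == (4, 4)
        perimeter = {
            (x, y)
            for x in range(2, 7)
            for y in range(2, 7)
            if x in (2, 6) or y in (2, 6)
        }
        assert set(region.contour) == perimeter
        assert len(region.contour) == 16
        assert_closed_cycle(region.contour)

    def test_all_foreground_has_no_holes(self):
        assert find_enclosed_regions(np.ones((6, 6))) == []

    def test_border_touching_background_is_not_enclosed(self):
        mask = np.ones((6, 6), dtype=np.uint8)
        mask[0:3, 3] = 0  # channel reaching the top border
        assert find_enclosed_regions(mask) == []

    def test_matches_flood_fill_oracle_on_random_blobs(self, rng):
        """Enclosed regions = border-unreachable background components."""
        for _ in range(25):
            mask = random_blob_mask(rng)
            regions = find_enclosed_regions(mask)
            found = {frozenset(map(tuple, r.pixels)) for r in regions}
            expected = set(enclosed_background_components(mask))
            assert found == expected
            for r in regions:
                assert_closed_cycle(r.contour)
                assert set(r.contour) <= set(map(tuple, r.pixels))


class TestQualifies:
    BOX = BoxSpec(cx=0, cy=0, bx=100, by=100)

    def test_equality_passes(self):
        assert qualifies(region_stub(20, 30, 40, 50), self.BOX, p=0.1)

    def test_one_pixel_short_fails(self):
        assert not qualifies(region_stub(20, 29, 40, 50), self.BOX, p=0.1)

    def test_outside_box_fails(self):
        box = BoxSpec(cx=10, cy=10, bx=100, by=100)
        assert not qualifies(region_stub(5, 40, 20, 60), box, p=0.1)
        assert not qualifies(region_stub(20, 115, 20, 60), box, p=0.1)

    def test_bottom_right_box_geometry(self):
        box = BoxSpec.bottom_right(256, 256, frac=0.6)
        assert (box.cx, box.cy) == (102, 102)
        assert (box.bx, box.by) == (154, 154)
        assert box.cx + box.bx <= 256 and box.cy + box.by <= 256


class TestRegionCentroid:
    def test_centered_square_hole(self):
        mask = np.ones((21, 21), dtype=np.uint8)
        mask[8:13, 8:13] = 0
        (region,) = find_enclosed_regions(mask)
        assert region_centroid(region) == (10.0, 10.0)

    def test_single_pixel(self):
        mask = np.ones((12, 12), dtype=np.uint8)
        mask[9, 4] = 0
        (region,) = find_enclosed_regions(mask)
        assert region_centroid(region) == (4.0, 9.0)

    def test_l_shaped_region_is_coordinate_mean(self):
        mask = np.ones((12, 12), dtype=np.uint8)
        hole = [(5, 5), (5, 6), (5, 7), (6, 7)]
        for x, y in hole:
            mask[y, x] = 0
        (region,) = find_enclosed_regions(mask)
        cx, cy = region_centroid(region)
        assert cx == pytest.approx(np.mean([p[0] for p in hole]))
        assert cy == pytest.approx(np.mean([p[1] for p in hole]))


def gapped_ring_scene(gap_level: float, size: int = 36):
    """Bright ring in the bottom-right box with one faint gap pixel.

    The enclosed hole only appears once l1 drops to or below ``gap_level``
    (the gap pixel then counts as tissue and seals the ring).
    """
    gray = np.full((size, size), 0.05)
    gray[18:31, 18:31] = 0.8
    gray[19:30, 19:30] = 0.05  # cavity
    gray[24, 18] = gap_level   # faint segment of the left wall
    return gray


class TestRecursiveSearch:
    def test_qualifying_at_initial_thresholds_takes_zero_decrements(self):
        gray = gapped_ring_scene(gap_level=0.8)  # no faint gap at all
        box = BoxSpec.bottom_right(36, 36, 0.6)
        result = recursive_search(gray, np.zeros_like(gray), box,
                                  p=0.1, c=0.03, l1_init=0.5, l2_init=0.2)
        assert result.decrements == (0, 0)
        assert result.l1_final == 0.5

    @pytest.mark.parametrize("gap_level", [0.3012, 0.4471, 0.137])
    def test_accepted_l1_is_largest_grid_value_admitting_the_gap(self, gap_level):
        gray = gapped_ring_scene(gap_level)
        gray_s = np.zeros_like(gray)
        box = BoxSpec.bottom_right(36, 36, 0.6)
        c, l1_init, l2_init = 0.03, 0.5, 0.2
        result = recursive_search(gray, gray_s, box, p=0.1, c=c,
                                  l1_init=l1_init, l2_init=l2_init)
        # brute-force scan of the full grid in nesting order agrees
        l1_ref, l2_ref, dec_ref = threshold_scan_oracle(
            gray, gray_s, box, 0.1, c, l1_init, l2_init)
        assert result.l1_final == pytest.approx(l1_ref, abs=1e-9)
        assert result.decrements == dec_ref
        # the accepted l1 is the largest grid value at or below the gap level
        assert result.l1_final <= gap_level
        assert result.l1_final + c > gap_level

    def test_all_zero_image_raises(self):
        gray = np.zeros((20, 20))
        box = BoxSpec.bottom_right(20, 20, 0.6)
        with pytest.raises(BoundaryNotFoundError, match="no atrium boundary"):
            recursive_search(gray, gray, box, p=0.1, c=0.05,
                             l1_init=0.2, l2_init=0.2)

    def test_iteration_count_is_bounded_by_grid_size(self, monkeypatch):
        gray = np.zeros((20, 20))
        box = BoxSpec.bottom_right(20, 20, 0.6)
        calls = {"n": 0}
        original = boundary_mod.find_enclosed_regions

        def counting(mask):
            calls["n"] += 1
            return original(mask)

        monkeypatch.setattr(boundary_mod, "find_enclosed_regions", counting)
        l1, l2, c = 0.21, 0.11, 0.05
        with pytest.raises(BoundaryNotFoundError):
            recursive_search(gray, gray, box, p=0.1, c=c,
                             l1_init=l1, l2_init=l2)
        bound = (int(np.ceil(l1 / c)) + 1) * (int(np.ceil(l2 / c)) + 1)
        assert 0 < calls["n"] <= bound

    def test_largest_region_wins_when_several_qualify(self):
        gray = np.full((40, 40), 0.05)
        gray[18:39, 18:39] = 0.8
        gray[20:26, 20:26] = 0.05   # small hole, spans 5 >= p*bx
        gray[28:38, 24:38] = 0.05   # large hole
        box = BoxSpec.bottom_right(40, 40, 0.6)
        result = recursive_search(gray, np.zeros_like(gray), box,
                                  p=0.2, c=0.05, l1_init=0.5, l2_init=0.2)
        assert result.region.area == 10 * 14
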