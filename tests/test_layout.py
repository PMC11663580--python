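import numpy as np
import pytest

from hullseg.layout import (
    Circle,
    cluster_centers,
    detect_circles,
    index_layout,
    roi_mask,
)

from _oracles import single_linkage_brute


def draw_rings(shape, centers, radius, value=1.0, thickness=3, bg=0.0):
    img = np.full(shape, bg)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cr, cc in centers:
        d = np.hypot(rows - cr, cols - cc)
        img[np.abs(d - radius) <= thickness / 2] = value
    return img


class TestDetectCircles:
    def test_finds_drawn_annuli_accurately(self):
        centers = [(40, 40), (40, 120), (40, 200), (120, 40), (120, 120), (120, 200)]
        img = draw_rings((160, 240), centers, radius=20)
        found = detect_circles(img, 15, 25, expected_n=6)
        assert len(found) == 6
        got = sorted(c.center for c in found)
        for (gr, gc), (tr, tc) in zip(got, sorted(centers)):
            assert np.hypot(gr - tr, gc - tc) <= 1.0
        assert all(abs(c.radius - 20) <= 2 for c in found)

    def test_blank_image_reports_zero_found(self):
        with pytest.raises(ValueError, match="found 0 of 6"):
            detect_circles(np.zeros((80, 80)), 10, 20, expected_n=6)

    def test_strongest_circles_win(self):
        strong = [(40, 40), (40, 120), (120, 40), (120, 120), (200, 40), (200, 120)]
        weak = [(40, 200), (200, 200)]  # partial arcs: weaker edge support
        img = draw_rings((240, 240), strong, radius=18, value=1.0)
        rows, cols = np.mgrid[0:240, 0:240]
        for cr, cc in weak:
            d = np.hypot(rows - cr, cols - cc)
            arc = (np.abs(d - 18) <= 1.5) & (np.arctan2(rows - cr, cols - cc) > 2.0)
            img[arc] = 1.0
        found = detect_circles(img, 14, 22, expected_n=6)
        got = {tuple(np.round(c.center).astype(int)) for c in found}
        for w in weak:
            assert all(np.hypot(g[0] - w[0], g[1] - w[1]) > 5 for g in got)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            detect_circles(np.zeros((10, 10)), 20, 10, 1)
        with pytest.raises(ValueError):
            detect_circles(np.zeros((10, 10)), 5, 10, 0)


class TestClusterCenters:
    def test_two_separated_triplets(self):
        pts = [(0, 0), (0, 50), (50, 25), (500, 0), (500, 50), (550, 25)]
        circles = [Circle(center=p, radius=10) for p in pts]
        labels = cluster_centers(circles, cut_distance=100)
        assert len(set(labels)) == 2
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    def test_all_within_cut_is_one_group(self):
        circles = [Circle(center=(i * 10.0, 0.0), radius=5) for i in range(5)]
        assert len(set(cluster_centers(circles, cut_distance=20))) == 1

    def test_matches_brute_force_single_linkage(self, rng):
        for _ in range(5):
            centers = rng.uniform(0, 300, size=(12, 2))
            cut = float(rng.uniform(20, 120))
            circles = [Circle(center=tuple(c), radius=5) for c in centers]
            labels = cluster_centers(circles, cut)
            want = single_linkage_brute(centers, cut)
            got = {}
            for i, lab in enumerate(labels):
                got.setdefault(lab, set()).add(i)
            assert sorted(map(sorted, got.values())) == sorted(
                map(sorted, want)
            )


class TestIndexLayout:
    def _grid(self, origin=(0.0, 0.0), rows=2, cols=2, spacing=100.0):
        return [
            (origin[0] + r * spacing, origin[1] + c * spacing)
            for r in range(rows)
            for c in range(cols)
        ]

    def test_row_major_reading_order(self):
        circles = [Circle(center=p, radius=10) for p in self._grid()]
        plate = index_layout(circles, np.ones(4, dtype=int))
        by_index = {u.unit_index: u.center for u in plate.units}
        assert by_index[1] == (0, 0) and by_index[2] == (0, 100)
        assert by_index[3] == (100, 0) and by_index[4] == (100, 100)

    def test_column_major_ordering(self):
        circles = [Circle(center=p, radius=10) for p in self._grid()]
        plate = index_layout(circles, np.ones(4, dtype=int), ordering="column-major")
        by_index = {u.unit_index: u.center for u in plate.units}
        assert by_index[1] == (0, 0) and by_index[2] == (100, 0)

    def test_stacked_groups_get_consecutive_ranges(self):
        top = self._grid((0, 0), rows=1, cols=3)
        bottom = self._grid((500, 0), rows=1, cols=3)
        circles = [Circle(center=p, radius=10) for p in top + bottom]
        groups = np.array([1, 1, 1, 2, 2, 2])
        plate = index_layout(circles, groups)
        for u in plate.units:
            if u.unit_index <= 3:
                assert u.center[0] == 0 and u.group_index == 1
            else:
                assert u.center[0] == 500 and u.group_index == 2

    def test_jitter_invariant_indexing(self, rng):
        grid = self._grid(rows=3, cols=4, spacing=100.0)
        circles = [Circle(center=p, radius=10) for p in grid]
        plate0 = index_layout(circles, np.ones(12, dtype=int))
        jit = [
            (r + rng.uniform(-3, 3), c + rng.uniform(-3, 3)) for r, c in grid
        ]
        plate1 = index_layout(
            [Circle(center=p, radius=10) for p in jit], np.ones(12, dtype=int)
        )
        for u0, u1 in zip(plate0.units, plate1.units):
            assert u0.unit_index == u1.unit_index
            assert np.hypot(
                u0.center[0] - u1.center[0], u0.center[1] - u1.center[1]
            ) < 5

    def test_invariant_to_input_order(self, rng):
        grid = self._grid(rows=2, cols=3)
        circles = [Circle(center=p, radius=10) for p in grid]
        plate0 = index_layout(circles, np.ones(6, dtype=int))
        perm = rng.permutation(6)
        shuffled = [circles[i] for i in perm]
        plate1 = index_layout(shuffled, np.ones(6, dtype=int))
        assert [u.center for u in plate0.units] == [
            u.center for u in plate1.units
        ]


class TestRoiMask:
    def test_single_disc_area(self):
        from hullseg.layout import LayoutUnit, PlateLayout

        plate = PlateLayout(
            units=[LayoutUnit(1, (50.0, 50.0), 10.0, 1)]
        )
        labels = roi_mask(plate, (100, 100))
        area = (labels == 1).sum()
        assert abs(area - np.pi * 100) / (np.pi * 100) < 0.02

    def test_overlapping_discs_resolved_by_nearest_center(self):
        from hullseg.layout import LayoutUnit, PlateLayout

        plate = PlateLayout(
            units=[
                LayoutUnit(1, (50.0, 40.0), 15.0, 1),
                LayoutUnit(2, (50.0, 60.0), 15.0, 1),
            ]
        )
        labels = roi_mask(plate, (100, 100))
        rows, cols = np.nonzero(labels)
        for r, c in zip(rows, cols):
            d1 = np.hypot(r - 50, c - 40)
            d2 = np.hypot(r - 50, c - 60)
            want = 1 if d1 < d2 else (2 if d2 < d1 else labels[r, c])
            assert labels[r, c] == want

    def test_dilation_grows_regions(self):
        from hullseg.layout import LayoutUnit, PlateLayout

        plate = PlateLayout(units=[LayoutUnit(1, (30.0, 30.0), 8.0, 1)])
        a0 = (roi_mask(plate, (60, 60), dilation=0) == 1).sum()
        a5 = (roi_mask(plate, (60, 60), dilation=5) == 1).sum()
        assert a5 > a0
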