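import numpy as np
import pytest
from scipy.spatial import ConvexHull

from hullseg.colorspace import LabImage
from hullseg.fixtures import make_color_cloud
from hullseg.hull import (
    DegenerateHullError,
    EmptyHullError,
    HullSpec,
    build_hull,
    classify,
    contains,
    distance_to_surface,
    hull_from_mask,
    merge_priors,
)

from conftest import random_cloud
from _oracles import contains_ray, distance_brute

TETRA = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
CUBE = np.array(
    [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=float
)


class TestBuildHull:
    def test_tetrahedron_has_four_facets(self):
        mesh = build_hull(TETRA, alpha=0)
        assert len(mesh.facets) == 4
        assert mesh.is_watertight()
        assert mesh.volume() == pytest.approx(1 / 6)

    def test_alpha_zero_equals_convex_hull_volume(self, rng):
        for _ in range(5):
            pts = random_cloud(rng, 25)
            mesh = build_hull(pts, alpha=0)
            assert mesh.volume() == pytest.approx(
                ConvexHull(pts).volume, rel=1e-9
            )

    def test_two_far_clusters_give_two_components(self, rng):
        c1 = random_cloud(rng, 8, spread=1.5, center=np.zeros(3))
        c2 = c1 + 100.0
        mesh = build_hull(np.vstack([c1, c2]), alpha=4.0)
        assert mesh.n_components == 2
        # brute-force edge-length bound over every facet edge
        assert mesh.edge_lengths().max() <= 4.0
        assert mesh.is_watertight()

    def test_alpha_monotonicity(self, rng):
        pts = random_cloud(rng, 40, spread=10)
        from scipy.spatial import Delaunay

        edges = []
        tri = Delaunay(pts)
        for tet in tri.simplices:
            for i in range(4):
                for j in range(i + 1, 4):
                    edges.append(np.linalg.norm(pts[tet[i]] - pts[tet[j]]))
        a1 = float(np.quantile(edges, 0.7))
        a2 = float(np.quantile(edges, 0.95))
        m1 = build_hull(pts, alpha=a1)
        m2 = build_hull(pts, alpha=a2)
        probes = rng.uniform(pts.min(), pts.max(), size=(300, 3))
        in1 = np.asarray(contains(probes, m1))
        in2 = np.asarray(contains(probes, m2))
        assert not (in1 & ~in2).any()  # solid grows with alpha

    @pytest.mark.parametrize(
        "pts,match",
        [
            (TETRA[:3], "4 vertices"),
            (np.column_stack([np.arange(5.0)] * 3), "collinear"),
            (np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 3, 0]], float), "coplanar"),
        ],
    )
    def test_degenerate_sets_raise_named_errors(self, pts, match):
        with pytest.raises(DegenerateHullError, match=match):
            build_hull(pts, alpha=0)

    def test_tiny_alpha_raises_empty_hull(self):
        with pytest.raises(EmptyHullError, match="empty hull"):
            build_hull(TETRA * 10, alpha=0.5)


class TestContains:
    def test_tetrahedron_inside_outside(self):
        mesh = build_hull(TETRA, alpha=0)
        assert contains(np.array([0.1, 0.1, 0.1]), mesh)
        assert not contains(np.array([5.0, 5.0, 5.0]), mesh)

    def test_vertex_and_barycenter_are_inside(self):
        mesh = build_hull(CUBE, alpha=0)
        assert contains(CUBE[0], mesh)  # boundary counts as inside
        bary = mesh.triangles().mean(axis=1)
        assert np.asarray(contains(bary, mesh)).all()

    def test_matches_ray_casting_oracle(self, rng):
        for _ in range(4):
            pts = random_cloud(rng, 15)
            mesh = build_hull(pts, alpha=0)
            lo, hi = pts.min() - 5, pts.max() + 5
            probes = rng.uniform(lo, hi, size=(100, 3))
            got = np.asarray(contains(probes, mesh))
            want = np.array(
                [contains_ray(p, mesh.points, mesh.facets) for p in probes]
            )
            assert (got == want).all()


class TestDistanceToSurface:
    def test_zero_on_vertices_and_barycenters(self, rng):
        pts = random_cloud(rng, 12)
        mesh = build_hull(pts, alpha=0)
        assert distance_to_surface(mesh.used_vertices(), mesh) == pytest.approx(
            np.zeros(len(mesh.used_vertices())), abs=1e-9
        )
        bary = mesh.triangles().mean(axis=1)
        assert np.max(distance_to_surface(bary, mesh)) < 1e-9

    def test_unit_cube_face_distance(self):
        mesh = build_hull(CUBE, alpha=0)
        assert distance_to_surface(np.array([2.0, 0.5, 0.5]), mesh) == pytest.approx(1.0)

    def test_matches_per_facet_brute_force(self, rng):
        for _ in range(4):
            pts = random_cloud(rng, 18)
            mesh = build_hull(pts, alpha=0)
            probes = rng.uniform(pts.min() - 10, pts.max() + 10, size=(80, 3))
            got = distance_to_surface(probes, mesh)
            want = np.array(
                [distance_brute(p, mesh.points, mesh.facets) for p in probes]
            )
            assert np.max(np.abs(got - want)) < 1e-9


class TestClassify:
    def test_inside_with_zero_delta(self):
        spec = HullSpec(vertices=CUBE, alpha=0, delta=0.0)
        mesh = spec.build()
        assert classify(np.array([0.5, 0.5, 0.5]), spec, mesh)

    def test_delta_threshold_is_sharp(self):
        # points constructed at exact analytic distances from the x=1 face
        spec = HullSpec(vertices=CUBE, alpha=0, delta=5.0)
        mesh = spec.build()
        assert classify(np.array([1.0 + 4.9, 0.5, 0.5]), spec, mesh)
        assert not classify(np.array([1.0 + 5.1, 0.5, 0.5]), spec, mesh)

    def test_huge_delta_accepts_everything(self, rng):
        spec = HullSpec(vertices=CUBE, alpha=0, delta=1e6)
        mesh = spec.build()
        probes = rng.uniform(-200, 200, size=(50, 3))
        assert np.asarray(classify(probes, spec, mesh)).all()

    def test_infinite_delta_rejected(self):
        with pytest.raises(ValueError):
            HullSpec(vertices=CUBE, alpha=0, delta=np.inf)


class TestHullFromMask:
    def _image_from_hull(self, rng, n=4000):
        # foreground colors drawn inside a known tetrahedral hull
        verts = np.array(
            [[40, -40, 20], [60, -40, 20], [50, -20, 20], [50, -33, 45]], float
        )
        # interior-weighted sampling: all colors strictly inside the hull
        w = rng.dirichlet(np.full(4, 3.0), size=n)
        fg = w @ verts
        lab = np.empty((n, 2, 3))
        lab[:, 0] = fg
        lab[:, 1] = [85.0, 0.0, 0.0]
        mask = np.zeros((n, 2), dtype=bool)
        mask[:, 0] = True
        return LabImage(lab), mask, fg

    def test_recovers_hull_containing_foreground(self, rng):
        lab, mask, fg = self._image_from_hull(rng)
        spec = hull_from_mask(lab, mask, min_pixels=1, alpha=0.0)
        mesh = spec.build()
        frac = np.asarray(contains(fg, mesh)).mean()
        assert frac >= 0.99

    def test_all_false_mask_raises(self):
        lab = LabImage(np.zeros((4, 4, 3)))
        with pytest.raises(DegenerateHullError):
            hull_from_mask(lab, np.zeros((4, 4), dtype=bool))

    def test_min_pixels_too_large_raises(self, rng):
        lab, mask, _ = self._image_from_hull(rng, n=100)
        with pytest.raises(DegenerateHullError, match="min_pixels"):
            hull_from_mask(lab, mask, min_pixels=10**6)


class TestMergePriors:
    def test_union_dedup_order(self):
        a, b, c = (1.0, 2.0, 3.0), (4.0, 5.0, 6.0), (7.0, 8.0, 9.0)
        assert merge_priors([a, b], [b, c]) == [a, b, c]
        assert merge_priors([], [c]) == [c]
        assert merge_priors([a], []) == [a]


class TestColorCloudFixture:
    def test_offset_points_at_exact_distance(self):
        mesh, surface, offset_pts, d, interior = make_color_cloud(offset=2.0)
        assert len(offset_pts) > 0
        got = distance_to_surface(offset_pts, mesh)
        assert np.max(np.abs(got - d)) < 1e-9
        assert np.max(distance_to_surface(surface, mesh)) < 1e-9
        assert np.asarray(contains(interior, mesh)).all()
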