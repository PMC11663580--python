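"""Target color volumes as hulls in CIELAB space.

A target color volume is described by a set of vertex colors plus an
``alpha`` parameter.  With ``alpha = 0`` the volume is the convex hull of
the vertices.  With ``alpha > 0`` it is an alpha hull: the vertices are
Delaunay-tetrahedralized, every tetrahedron with an edge longer than
``alpha`` (in ΔE units) is discarded, and the boundary triangles of the
retained solid form the surface.  This permits concave surfaces and
disjoint components, which matter when target colors form several separated
clusters (e.g. green laminae plus red stipes).

Pixels are classified against the volume by containment or by Euclidean
distance (ΔE) from the triangulated surface, thresholded at ``delta``.

Containment uses the generalized winding number (summed signed solid
angles), which is robust for watertight, consistently outward-oriented
meshes and extends naturally to unions of disjoint components.  Surface
distance is an exact vectorized point-to-triangle minimum over all facets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .colorspace import LabImage, filter_voxels, voxelize

__all__ = [
    "DegenerateHullError",
    "EmptyHullError",
    "HullSpec",
    "FacetMesh",
    "build_hull",
    "contains",
    "distance_to_surface",
    "classify",
    "hull_from_mask",
    "merge_priors",
]

# Points closer to the surface than this count as on-boundary (inside).
_BOUNDARY_TOL = 1e-9

# Tetrahedra edge index pairs (4 vertices -> 6 edges).
_TET_EDGES = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
# Faces of a tetrahedron, each paired with its opposite vertex index.
_TET_FACES = [((1, 2, 3), 0), ((0, 2, 3), 1), ((0, 1, 3), 2), ((0, 1, 2), 3)]


class DegenerateHullError(ValueError):
    """Vertex set cannot support a 3D hull (too few or not full-rank)."""


class EmptyHullError(ValueError):
    """No tetrahedron survives the alpha edge-length limit."""


@dataclass
class HullSpec:
    """User-facing description of a target color volume.

    Attributes
    ----------
    vertices : (N, 3) Lab coordinates of the hull vertices.
    alpha : maximum facet edge length in ΔE units; 0 means unlimited
        (convex hull).
    delta : ΔE threshold from the hull surface; pixels within ``delta`` of
        the surface (or inside the hull) are classified as target.
    """

    vertices: np.ndarray
    alpha: float = 0.0
    delta: float = 5.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.delta < 0 or not np.isfinite(self.delta):
            raise ValueError("delta must be finite and >= 0")

    def build(self) -> "FacetMesh":
        return build_hull(self.vertices, self.alpha)


@dataclass
class FacetMesh:
    """Triangulated hull surface, possibly with several disjoint components.

    ``facets`` are index triples into ``points``, consistently oriented so
    facet normals point out of the enclosed solid.  ``components`` assigns
    each facet to a connected component (facets sharing an edge).
    """

    points: np.ndarray
    facets: np.ndarray
    components: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.facets = np.asarray(self.facets, dtype=np.int64).reshape(-1, 3)
        if self.components is None:
            self.components = _facet_components(self.facets)
        else:
            self.components = np.asarray(self.components, dtype=np.int64)

    @property
    def n_components(self) -> int:
        return int(self.components.max()) + 1 if len(self.facets) else 0

    def triangles(self) -> np.ndarray:
        """(F, 3, 3) vertex coordinates per facet."""
        return self.points[self.facets]

    def edge_lengths(self) -> np.ndarray:
        """(F, 3) facet edge lengths."""
        tri = self.triangles()
        return np.linalg.norm(tri - np.roll(tri, -1, axis=1), axis=2)

    def volume(self) -> float:
        """Enclosed volume via the divergence theorem (sum of signed
        tetrahedra from the origin; exact for watertight outward meshes)."""
        tri = self.triangles()
        return float(
            np.abs(
                np.einsum(
                    "ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])
                ).sum()
            )
            / 6.0
        )

    def is_watertight(self) -> bool:
        """Every edge shared by exactly two facets of its component."""
        edges: dict[tuple[int, int], int] = {}
        for f in self.facets:
            for i in range(3):
                e = (int(f[i]), int(f[(i + 1) % 3]))
                e = (min(e), max(e))
                edges[e] = edges.get(e, 0) + 1
        return all(v == 2 for v in edges.values())

    def used_vertices(self) -> np.ndarray:
        """Lab coordinates of vertices referenced by at least one facet."""
        return self.points[np.unique(self.facets)]


def _facet_components(facets: np.ndarray) -> np.ndarray:
    """Label facets by connected component (shared-edge adjacency)."""
    n = len(facets)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edge_owner: dict[tuple[int, int], int] = {}
    for fi, f in enumerate(facets):
        for i in range(3):
            e = (int(f[i]), int(f[(i + 1) % 3]))
            e = (min(e), max(e))
            if e in edge_owner:
                ra, rb = find(edge_owner[e]), find(fi)
                if ra != rb:
                    parent[rb] = ra
            else:
                edge_owner[e] = fi
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def _check_full_rank(points: np.ndarray) -> None:
    if len(points) < 4:
        raise DegenerateHullError(
            f"degenerate hull: need >= 4 vertices for a 3D hull, "
            f"got {len(points)}"
        )
    centered = points - points.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(points).max()))
    if rank < 3:
        kind = {0: "coincident", 1: "collinear", 2: "coplanar"}[int(rank)]
        raise DegenerateHullError(
            f"degenerate hull: vertex set is {kind} (affine rank {rank} < 3)"
        )


def _orient_outward(points: np.ndarray, facets: list, inner_ref: np.ndarray) -> np.ndarray:
    """Flip facets so normals point away from per-facet interior reference
    points (``inner_ref``, one per facet)."""
    out = np.asarray(facets, dtype=np.int64).reshape(-1, 3).copy()
    tri = points[out]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    to_ref = inner_ref - tri[:, 0]
    flip = np.einsum("ij,ij->i", normals, to_ref) > 0
    out[flip] = out[flip][:, [0, 2, 1]]
    return out


def build_hull(vertices: np.ndarray, alpha: float = 0.0) -> FacetMesh:
    """Build the triangulated hull surface of a Lab vertex set.

    With ``alpha = 0``, the convex hull.  With ``alpha > 0``, the boundary
    of the union of Delaunay tetrahedra all of whose six edges are at most
    ``alpha`` long; tetrahedra with a longer edge are discarded, so the
    surface may be concave and split into disjoint components.

    Raises
    ------
    DegenerateHullError : fewer than 4 vertices, or collinear/coplanar set.
    EmptyHullError : ``alpha > 0`` so small no tetrahedron survives.
    """
    pts = np.asarray(vertices, dtype=float).reshape(-1, 3)
    _check_full_rank(pts)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")

    if alpha == 0:
        try:
            hull = ConvexHull(pts)
        except QhullError as exc:  # full-rank check should catch first
            raise DegenerateHullError(f"degenerate hull: {exc}") from exc
        centroid = pts[np.unique(hull.simplices)].mean(axis=0)
        ref = np.broadcast_to(centroid, (len(hull.simplices), 3))
        facets = _orient_outward(pts, hull.simplices, ref)
        return FacetMesh(points=pts, facets=facets)

    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegenerateHullError(f"degenerate hull: {exc}") from exc
    tets = tri.simplices
    # keep tetrahedra whose six edges are all <= alpha
    keep = np.ones(len(tets), dtype=bool)
    for i, j in _TET_EDGES:
        d = np.linalg.norm(pts[tets[:, i]] - pts[tets[:, j]], axis=1)
        keep &= d <= alpha
    kept = tets[keep]
    if len(kept) == 0:
        raise EmptyHullError(
            f"empty hull at alpha={alpha}: no tetrahedron has all edges "
            f"<= alpha"
        )
    # boundary faces appear in exactly one kept tetrahedron
    face_count: dict[tuple[int, int, int], tuple[tuple[int, int, int], int]] = {}
    seen: dict[tuple[int, int, int], int] = {}
    for tet in kept:
        for face_idx, opp_idx in _TET_FACES:
            face = tuple(int(tet[i]) for i in face_idx)
            key = tuple(sorted(face))
            seen[key] = seen.get(key, 0) + 1
            face_count[key] = (face, int(tet[opp_idx]))
    boundary = [face_count[k] for k, c in seen.items() if c == 1]
    facets = [f for f, _ in boundary]
    opp = np.array([pts[o] for _, o in boundary])
    oriented = _orient_outward(pts, facets, opp)
    return FacetMesh(points=pts, facets=oriented)


def _point_triangle_dist2(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Squared distances from P points to F triangles, shape (P, F).

    Barycentric projection is used where the foot falls inside the
    triangle; otherwise the minimum over the three edge segments.
    """
    v0 = tri[:, 0]
    e0 = tri[:, 1] - v0
    e1 = tri[:, 2] - v0
    a = np.einsum("ij,ij->i", e0, e0)
    b = np.einsum("ij,ij->i", e0, e1)
    c = np.einsum("ij,ij->i", e1, e1)
    det = np.maximum(a * c - b * b, 1e-300)

    d = points[:, None, :] - v0[None, :, :]  # (P, F, 3)
    d0 = np.einsum("pfj,fj->pf", d, e0)
    d1 = np.einsum("pfj,fj->pf", d, e1)
    s = (c * d0 - b * d1) / det
    t = (a * d1 - b * d0) / det
    inside = (s >= 0) & (t >= 0) & (s + t <= 1)

    # face region: residual after projecting onto the triangle plane
    foot = s[..., None] * e0[None] + t[..., None] * e1[None]
    face_d2 = np.einsum("pfj,pfj->pf", d - foot, d - foot)

    # edge segments (v0->v1, v0->v2, v1->v2)
    def seg_d2(origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
        dd = np.einsum("ij,ij->i", direction, direction)
        w = points[:, None, :] - origin[None, :, :]
        u = np.clip(
            np.einsum("pfj,fj->pf", w, direction) / np.maximum(dd, 1e-300),
            0.0,
            1.0,
        )
        r = w - u[..., None] * direction[None]
        return np.einsum("pfj,pfj->pf", r, r)

    edge_d2 = np.minimum(
        seg_d2(v0, e0),
        np.minimum(seg_d2(v0, e1), seg_d2(tri[:, 1], tri[:, 2] - tri[:, 1])),
    )
    return np.where(inside, np.minimum(face_d2, edge_d2), edge_d2)


def _chunked(n_points: int, n_facets: int, budget: int = 4_000_000) -> int:
    return max(1, min(n_points, budget // max(1, n_facets)))


def distance_to_surface(point: np.ndarray, mesh: FacetMesh) -> np.ndarray | float:
    """Minimum Euclidean (ΔE) distance from point(s) to the hull surface.

    Exact point-to-triangle minimum over all facets; handles closest
    points on faces, edges, and vertices.  Accepts a single (3,) point or
    an (N, 3) array.
    """
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    pts = pts.reshape(-1, 3)
    tri = mesh.triangles()
    out = np.empty(len(pts))
    step = _chunked(len(pts), len(tri))
    for i in range(0, len(pts), step):
        d2 = _point_triangle_dist2(pts[i : i + step], tri)
        out[i : i + step] = np.sqrt(np.maximum(d2.min(axis=1), 0.0))
    return float(out[0]) if single else out


def _winding_number(points: np.ndarray, mesh: FacetMesh) -> np.ndarray:
    """Generalized winding number (in units of full 4π turns) per point."""
    tri = mesh.triangles()
    out = np.zeros(len(points))
    step = _chunked(len(points), len(tri))
    for i in range(0, len(points), step):
        p = points[i : i + step]
        a = tri[None, :, 0] - p[:, None]
        b = tri[None, :, 1] - p[:, None]
        c = tri[None, :, 2] - p[:, None]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        numer = np.einsum("pfj,pfj->pf", a, np.cross(b, c))
        denom = (
            la * lb * lc
            + np.einsum("pfj,pfj->pf", a, b) * lc
            + np.einsum("pfj,pfj->pf", b, c) * la
            + np.einsum("pfj,pfj->pf", c, a) * lb
        )
        omega = 2.0 * np.arctan2(numer, denom)
        out[i : i + step] = omega.sum(axis=1) / (4.0 * np.pi)
    return out


def contains(point: np.ndarray, mesh: FacetMesh) -> np.ndarray | bool:
    """True where the point is inside or on the hull surface.

    Union semantics over disjoint components: inside any component counts.
    Points on the boundary (surface distance ~0) count as inside.
    """
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    pts = pts.reshape(-1, 3)
    w = _winding_number(pts, mesh)
    inside = np.abs(w) > 0.5
    # resolve boundary points, where the winding number is ambiguous
    near = ~inside
    if near.any():
        d = distance_to_surface(pts[near], mesh)
        inside[near] = np.asarray(d) <= _BOUNDARY_TOL
    return bool(inside[0]) if single else inside


def classify(point: np.ndarray, spec: HullSpec, mesh: FacetMesh | None = None):
    """Target/not-target classification of Lab point(s).

    A point is target iff it is inside the hull or within ``spec.delta``
    ΔE of the hull surface.
    """
    if mesh is None:
        mesh = spec.build()
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    pts = pts.reshape(-1, 3)
    d = np.asarray(distance_to_surface(pts, mesh)).reshape(-1)
    target = d <= spec.delta
    far = ~target
    if far.any():
        target[far] = np.abs(_winding_number(pts[far], mesh)) > 0.5
    return bool(target[0]) if single else target


def hull_from_mask(
    lab: LabImage,
    mask: np.ndarray,
    min_pixels: int = 20,
    alpha: float = 0.0,
    delta: float = 5.0,
    bin_size: float = 1.0,
) -> HullSpec:
    """Automate hull construction from a known-foreground mask.

    Masked (foreground) pixel colors are voxelized, voxels with fewer than
    ``min_pixels`` members are dropped, and the surviving voxel centers
    become candidate vertices; the hull is built at ``alpha`` and the spec
    keeps only the vertices the surface actually uses.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != lab.lab.shape[:2]:
        raise ValueError("mask dimensions must match image")
    masked = LabImage(lab=lab.lab, valid=mask & lab.valid)
    grid = filter_voxels(voxelize(masked, bin_size=bin_size), min_pixels)
    centers = grid.centers()
    if len(centers) < 4:
        raise DegenerateHullError(
            f"degenerate hull: only {len(centers)} voxels survive "
            f"min_pixels={min_pixels}"
        )
    mesh = build_hull(centers, alpha)
    return HullSpec(vertices=mesh.used_vertices(), alpha=alpha, delta=delta)


def merge_priors(selected: list, priors: list) -> list:
    """Deduplicated union of vertex lists, preserving first-seen order.

    "Priors" are vertices carried over from earlier images or a loaded
    configuration; they join the currently selected voxels as candidate
    hull vertices so a hull generalizes across a series.
    """
    out: list = []
    seen: set = set()
    for item in list(selected) + list(priors):
        key = tuple(np.asarray(item, dtype=float).reshape(3))
        if key not in seen:
            seen.add(key)
            out.append(tuple(float(v) for v in key))
    return out
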