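"""Synthetic fixtures with known ground truth.

Generates image series that emulate a multiplexed phenotyping array: a
grid of dark circular fiducial rings on a light background, one growing
"blob" of target-colored pixels per unit, arranged in groups (trays).
Target colors are sampled strictly inside a known Lab hull; background and
marker colors sit a stated ΔE margin outside it, so segmentation of a
well-formed fixture is exact and every downstream quantity (mask, per-unit
area, growth rate) has a generator-side truth computed independently of
the analysis pipeline.

Everything is a deterministic function of the fixture spec (including its
seed).  Blobs are discs with sinusoidal boundary perturbation: irregular
enough to exercise morphology, simple enough that truth areas come from
the generator's own pixel counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
from PIL import Image

from .colorspace import lab_to_srgb

__all__ = [
    "FixtureSpec",
    "FixtureSeries",
    "make_image_series",
    "make_color_cloud",
    "write_series",
]

# Default ground-truth hull: corners of a cuboid in the green region of Lab.
_DEFAULT_HULL = np.array(
    [
        [38.0, -42.0, 22.0],
        [38.0, -42.0, 36.0],
        [38.0, -28.0, 22.0],
        [38.0, -28.0, 36.0],
        [52.0, -42.0, 22.0],
        [52.0, -42.0, 36.0],
        [52.0, -28.0, 22.0],
        [52.0, -28.0, 36.0],
    ]
)


@dataclass
class FixtureSpec:
    """Fully determines a synthetic series given its seed.

    Units are laid out on a rows x cols grid per group; groups are stacked
    vertically with ``group_gap`` extra pixels between them.  Per-unit
    initial areas ``a0`` (px) and growth rates ``rgr`` (per day) may be
    scalars or per-unit arrays; areas follow a0 * exp(rgr * t) with
    multiplicative log-normal noise of sigma ``noise_sigma``.
    """

    seed: int = 0
    rows: int = 2
    cols: int = 3
    groups: int = 2
    spacing: int = 64
    group_gap: int = 40
    marker_radius: int = 22
    ring_thickness: int = 3
    jitter: float = 0.0
    n_timepoints: int = 6
    dt_days: float = 1.0
    a0: float | np.ndarray = 120.0
    rgr: float | np.ndarray = 0.25
    noise_sigma: float = 0.0
    hull_vertices: np.ndarray = field(
        default_factory=lambda: _DEFAULT_HULL.copy()
    )
    color_shrink: float = 0.5  # sampling cuboid shrink toward the center
    background_lab: tuple[float, float, float] = (70.0, 0.0, 0.0)
    background_spread: float = 2.0
    marker_lab: tuple[float, float, float] = (8.0, 0.0, 0.0)

    @property
    def n_units(self) -> int:
        return self.rows * self.cols * self.groups

    @property
    def recommended_cut(self) -> float:
        """Single-linkage cut separating groups: halfway between the
        intra-group spacing and the closest inter-group distance."""
        return self.spacing + self.group_gap / 2.0

    def unit_param(self, value, unit: int) -> float:
        arr = np.asarray(value, dtype=float)
        return float(arr.flat[unit % arr.size]) if arr.size > 1 else float(arr)

    def canvas_shape(self) -> tuple[int, int]:
        h = self.groups * self.rows * self.spacing + (
            self.groups - 1
        ) * self.group_gap + self.spacing // 2
        w = self.cols * self.spacing + self.spacing // 2
        return h, w

    def grid_centers(self, rng: np.random.Generator) -> np.ndarray:
        """(n_units, 2) integer (row, col) centers in reading order, with
        integer jitter applied; also defines the truth unit indexing."""
        centers = []
        margin = self.spacing // 2 + self.spacing // 4
        for g in range(self.groups):
            top = g * (self.rows * self.spacing + self.group_gap)
            for r in range(self.rows):
                for c in range(self.cols):
                    centers.append(
                        (
                            top + margin // 2 + r * self.spacing + self.spacing // 4,
                            margin // 2 + c * self.spacing + self.spacing // 4,
                        )
                    )
        centers = np.array(centers, dtype=float)
        if self.jitter > 0:
            centers += rng.integers(
                -int(round(self.jitter)),
                int(round(self.jitter)) + 1,
                size=centers.shape,
            )
        return np.round(centers).astype(int)


@dataclass
class FixtureSeries:
    """Generated images plus every ground-truth quantity."""

    spec: FixtureSpec
    images: list  # uint8 sRGB arrays
    masks: list  # bool truth foreground masks
    times: np.ndarray  # days
    centers: np.ndarray  # (n_units, 2) truth centers, reading order
    radii: np.ndarray  # (n_units,) marker radii
    unit_groups: np.ndarray  # (n_units,) 1-based truth group per unit
    truth_areas: np.ndarray  # (n_timepoints, n_units) generator pixel counts
    truth_rgr: np.ndarray  # (n_units,) generating growth rates


def _blob_pixels(
    shape: tuple[int, int],
    center: tuple[float, float],
    area: float,
    phase: float,
    amp: float = 0.12,
    lobes: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Rows/cols of a perturbed disc of approximately the requested area.

    Radius r(θ) = r0 (1 + amp sin(lobes θ + phase)); mean enclosed area is
    π r0² (1 + amp²/2), solved for r0.  Truth areas are nevertheless
    counted from the rasterized pixels, never from this formula.
    """
    r0 = np.sqrt(area / (np.pi * (1 + amp**2 / 2)))
    rmax = int(np.ceil(r0 * (1 + amp))) + 1
    cr, cc = center
    r_lo = max(0, int(cr) - rmax)
    r_hi = min(shape[0], int(cr) + rmax + 1)
    c_lo = max(0, int(cc) - rmax)
    c_hi = min(shape[1], int(cc) + rmax + 1)
    rows, cols = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    dy = rows - cr
    dx = cols - cc
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    inside = rho <= r0 * (1 + amp * np.sin(lobes * theta + phase))
    return rows[inside], cols[inside]


def _draw_ring(
    canvas: np.ndarray,
    center: tuple[int, int],
    radius: int,
    thickness: int,
    lab: tuple[float, float, float],
) -> None:
    h, w = canvas.shape[:2]
    rows, cols = np.mgrid[0:h, 0:w]
    d = np.hypot(rows - center[0], cols - center[1])
    ring = np.abs(d - radius) <= thickness / 2
    canvas[ring] = lab


def _sample_cuboid(
    rng: np.random.Generator, vertices: np.ndarray, shrink: float, n: int
) -> np.ndarray:
    lo = vertices.min(axis=0)
    hi = vertices.max(axis=0)
    center = (lo + hi) / 2
    half = (hi - lo) / 2 * (1.0 - shrink)
    return center + rng.uniform(-1, 1, size=(n, 3)) * half


def make_image_series(spec: FixtureSpec) -> FixtureSeries:
    """Generate the full series with ground truth.

    Raises
    ------
    ValueError : blob geometry infeasible (a blob would overlap its
        fiducial ring or leave its grid cell).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.canvas_shape()
    centers = spec.grid_centers(rng)
    n_units = spec.n_units
    radii = np.full(n_units, spec.marker_radius, dtype=float)
    unit_groups = np.repeat(np.arange(1, spec.groups + 1), spec.rows * spec.cols)
    times = np.arange(spec.n_timepoints, dtype=float) * spec.dt_days
    phases = rng.uniform(0, 2 * np.pi, size=n_units)
    truth_rgr = np.array(
        [spec.unit_param(spec.rgr, u) for u in range(n_units)]
    )
    a0 = np.array([spec.unit_param(spec.a0, u) for u in range(n_units)])
    noise = (
        np.exp(rng.normal(0.0, spec.noise_sigma, size=(spec.n_timepoints, n_units)))
        if spec.noise_sigma > 0
        else np.ones((spec.n_timepoints, n_units))
    )

    # feasibility: perturbed blob must stay inside the fiducial ring
    amp = 0.12
    max_area = (a0[None] * np.exp(truth_rgr[None] * times[:, None]) * noise).max(axis=0)
    max_r = np.sqrt(max_area / (np.pi * (1 + amp**2 / 2))) * (1 + amp)
    limit = spec.marker_radius - spec.ring_thickness - 1
    if (max_r > limit).any():
        raise ValueError(
            f"infeasible geometry: blob radius up to {max_r.max():.1f} px "
            f"exceeds the {limit} px available inside the fiducial ring"
        )

    images, masks = [], []
    truth_areas = np.zeros((spec.n_timepoints, n_units), dtype=int)
    for ti, t in enumerate(times):
        lab = np.empty(shape + (3,), dtype=float)
        lab[..., 0] = spec.background_lab[0]
        lab[..., 1] = spec.background_lab[1]
        lab[..., 2] = spec.background_lab[2]
        lab += rng.uniform(
            -spec.background_spread, spec.background_spread, size=lab.shape
        )
        for u in range(n_units):
            _draw_ring(
                lab,
                tuple(centers[u]),
                spec.marker_radius,
                spec.ring_thickness,
                spec.marker_lab,
            )
        mask = np.zeros(shape, dtype=bool)
        for u in range(n_units):
            area = a0[u] * np.exp(truth_rgr[u] * t) * noise[ti, u]
            rr, cc = _blob_pixels(shape, tuple(centers[u]), area, phases[u], amp=amp)
            lab[rr, cc] = _sample_cuboid(
                rng, spec.hull_vertices, spec.color_shrink, len(rr)
            )
            mask[rr, cc] = True
            truth_areas[ti, u] = len(rr)  # generator's own count
        images.append(lab_to_srgb(lab))
        masks.append(mask)
    return FixtureSeries(
        spec=spec,
        images=images,
        masks=masks,
        times=times,
        centers=centers,
        radii=radii,
        unit_groups=unit_groups,
        truth_areas=truth_areas,
        truth_rgr=truth_rgr,
    )


def make_color_cloud(
    vertices: np.ndarray | None = None,
    alpha: float = 0.0,
    offset: float = 2.0,
    seed: int = 0,
):
    """Labeled Lab point sets at known distances from a truth hull surface.

    Returns (mesh, surface_points, offset_points, offset_distance,
    interior_points): hull vertices lie at distance 0; ``offset_points``
    are facet barycenters pushed outward along facet normals, kept only
    when the generator's own exhaustive point-triangle scan confirms the
    nearest surface point is the source barycenter (distance exactly
    ``offset``); interior points are barycenter/centroid mixes strictly
    inside.
    """
    from .hull import build_hull  # local import to keep fixture deps light

    verts = _DEFAULT_HULL.copy() if vertices is None else np.asarray(vertices)
    mesh = build_hull(verts, alpha)
    tri = mesh.triangles()
    bary = tri.mean(axis=1)
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    candidates = bary + offset * normals

    def _exhaustive_dist(p: np.ndarray) -> float:
        best = np.inf
        for t3 in tri:
            best = min(best, _point_tri_dist(p, t3))
        return best

    keep = np.array(
        [abs(_exhaustive_dist(p) - offset) < 1e-9 for p in candidates]
    )
    offset_points = candidates[keep]
    centroid = mesh.used_vertices().mean(axis=0)
    interior = bary + 0.5 * (centroid - bary)
    surface = mesh.used_vertices()
    return mesh, surface, offset_points, offset, interior


def _point_tri_dist(p: np.ndarray, tri: np.ndarray) -> float:
    """Scalar exact point-to-triangle distance (generator-side check)."""
    v0, v1, v2 = tri
    e0, e1 = v1 - v0, v2 - v0
    d = p - v0
    a, b, c = e0 @ e0, e0 @ e1, e1 @ e1
    d0, d1 = e0 @ d, e1 @ d
    det = a * c - b * b
    s, t = (c * d0 - b * d1) / det, (a * d1 - b * d0) / det
    if s >= 0 and t >= 0 and s + t <= 1:
        return float(np.linalg.norm(d - s * e0 - t * e1))

    def seg(q, o, e):
        u = np.clip((q - o) @ e / (e @ e), 0, 1)
        return float(np.linalg.norm(q - o - u * e))

    return min(seg(p, v0, e0), seg(p, v0, e1), seg(p, v1, v2 - v1))


def write_series(
    series: FixtureSeries,
    out_dir: str | Path,
    start: datetime | None = None,
    write_masks: bool = True,
) -> list[Path]:
    """Write the series as timestamped PNGs (plus truth masks).

    Filenames embed the capture time as ``img_YYYYmmdd_HHMMSS.png`` so the
    pipeline's timestamp regex can recover the time axis.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    start = start or datetime(2024, 3, 1)
    paths = []
    for img, mask, t in zip(series.images, series.masks, series.times):
        ts = (start + timedelta(days=float(t))).strftime("%Y%m%d_%H%M%S")
        p = out_dir / f"img_{ts}.png"
        Image.fromarray(img).save(p)
        if write_masks:
            Image.fromarray((mask * 255).astype(np.uint8)).save(
                out_dir / f"mask_{ts}.png"
            )
        paths.append(p)
    return paths
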