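"""Plate layout from circular fiducial markers.

Multiplexed arrays (pots in trays, lamina discs under retaining rings)
carry circular markers that locate each experimental unit.  Markers are
detected with a circular Hough transform on the luminance edge map, their
centers are clustered (single linkage, distance cut) into groups such as
trays, and units are indexed 1..N in reading order across groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

__all__ = [
    "Circle",
    "LayoutUnit",
    "PlateLayout",
    "detect_circles",
    "cluster_centers",
    "index_layout",
    "roi_mask",
]


@dataclass(frozen=True)
class Circle:
    """A detected circular marker: subpixel (row, col) center, radius in
    pixels, and the detector accumulator score."""

    center: tuple[float, float]
    radius: float
    score: float = 0.0


@dataclass(frozen=True)
class LayoutUnit:
    unit_index: int  # 1-based, unique, contiguous
    center: tuple[float, float]
    radius: float
    group_index: int  # 1-based


@dataclass
class PlateLayout:
    """Indexed regions of interest grouped into clusters."""

    units: list[LayoutUnit] = field(default_factory=list)
    grouping_cut: float = 0.0
    ordering: str = "row-major"

    @property
    def n_groups(self) -> int:
        return len({u.group_index for u in self.units})

    def centers(self) -> np.ndarray:
        return np.array([u.center for u in self.units])


def detect_circles(
    image: np.ndarray,
    r_min: int,
    r_max: int,
    expected_n: int,
    sigma: float = 2.0,
) -> list[Circle]:
    """Find the ``expected_n`` strongest non-overlapping circles.

    Runs a circular Hough transform over the Canny edge map of a grayscale
    (luminance) image for radii in [r_min, r_max], then greedily keeps the
    highest-accumulator circles whose centers are more than ``r_min``
    apart.  Score ties break toward the top-left-most center.

    Raises
    ------
    ValueError : fewer than ``expected_n`` acceptable circles found,
        reporting how many were found.
    """
    if r_min > r_max:
        raise ValueError("r_min must be <= r_max")
    if expected_n < 1:
        raise ValueError("expected_n must be >= 1")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_circles expects a single-channel image")
    if img.max() > 1.0:
        img = img / 255.0
    edges = canny(img, sigma=sigma)
    radii = np.arange(int(r_min), int(r_max) + 1)
    accum = hough_circle(edges, radii)
    # take an excess of peaks, then enforce the separation rule greedily
    scores, cols, rows, rads = hough_circle_peaks(
        accum,
        radii,
        total_num_peaks=expected_n * 4,
        min_xdistance=int(r_min),
        min_ydistance=int(r_min),
    )
    order = np.lexsort((cols, rows, -scores))  # score desc, then top-left
    chosen: list[Circle] = []
    for i in order:
        c = (float(rows[i]), float(cols[i]))
        if all(
            np.hypot(c[0] - k.center[0], c[1] - k.center[1]) > r_min
            for k in chosen
        ):
            chosen.append(Circle(center=c, radius=float(rads[i]), score=float(scores[i])))
        if len(chosen) == expected_n:
            break
    if len(chosen) < expected_n:
        raise ValueError(
            f"layout detection failed: found {len(chosen)} of "
            f"{expected_n} expected circles"
        )
    return chosen


def cluster_centers(circles: list[Circle], cut_distance: float) -> np.ndarray:
    """Single-linkage clustering of circle centers, cut at ``cut_distance``.

    Returns a 1-based group label per circle; the number of groups is
    emergent from the cut.
    """
    if cut_distance <= 0:
        raise ValueError("cut_distance must be > 0")
    centers = np.array([c.center for c in circles], dtype=float)
    if len(centers) == 1:
        return np.array([1])
    z = linkage(pdist(centers), method="single")
    return fcluster(z, t=cut_distance, criterion="distance")


def _band_rows(values: np.ndarray, tol: float) -> np.ndarray:
    """Group sorted scalar positions into bands within ``tol`` of the
    running band start; returns a band id per input element."""
    order = np.argsort(values, kind="stable")
    bands = np.zeros(len(values), dtype=int)
    band = 0
    start = values[order[0]] if len(values) else 0.0
    for rank, i in enumerate(order):
        if rank and values[i] - start > tol:
            band += 1
            start = values[i]
        bands[i] = band
    return bands


def index_layout(
    circles: list[Circle],
    groups: np.ndarray,
    ordering: str = "row-major",
    cut_distance: float = 0.0,
) -> PlateLayout:
    """Assign 1..N unit indices across groups in reading order.

    Groups are ordered by centroid, top-to-bottom then left-to-right.
    Within a group, centers are banded into rows (or columns for
    column-major ordering) with tolerance half the median nearest-neighbor
    spacing, so a few pixels of grid jitter cannot permute the indexing,
    then sorted band-major.  Invariant to input circle order.
    """
    if ordering not in ("row-major", "column-major"):
        raise ValueError("ordering must be 'row-major' or 'column-major'")
    if not circles:
        raise ValueError("no circles to index")
    centers = np.array([c.center for c in circles], dtype=float)
    radii = np.array([c.radius for c in circles], dtype=float)
    groups = np.asarray(groups)

    if len(centers) > 1:
        d = pdist(centers)
        sq = np.zeros((len(centers), len(centers)))
        sq[np.triu_indices(len(centers), 1)] = d
        sq += sq.T
        np.fill_diagonal(sq, np.inf)
        band_tol = 0.5 * float(np.median(sq.min(axis=1)))
    else:
        band_tol = 0.0

    group_ids = sorted(set(int(g) for g in groups))
    centroids = {
        g: centers[groups == g].mean(axis=0) for g in group_ids
    }
    group_order = sorted(
        group_ids, key=lambda g: (round(centroids[g][0], 6), round(centroids[g][1], 6))
    )

    units: list[LayoutUnit] = []
    next_index = 1
    primary, secondary = (0, 1) if ordering == "row-major" else (1, 0)
    for new_gid, g in enumerate(group_order, start=1):
        idx = np.flatnonzero(groups == g)
        sub = centers[idx]
        bands = _band_rows(sub[:, primary], band_tol)
        # sort by (band, secondary coordinate, primary, radius) — stable
        order = sorted(
            range(len(idx)),
            key=lambda i: (
                bands[i],
                sub[i, secondary],
                sub[i, primary],
                radii[idx[i]],
            ),
        )
        for i in order:
            units.append(
                LayoutUnit(
                    unit_index=next_index,
                    center=(float(sub[i, 0]), float(sub[i, 1])),
                    radius=float(radii[idx[i]]),
                    group_index=new_gid,
                )
            )
            next_index += 1
    return PlateLayout(units=units, grouping_cut=cut_distance, ordering=ordering)


def roi_mask(
    layout: PlateLayout, shape: tuple[int, int], dilation: float = 0.0
) -> np.ndarray:
    """Labeled raster of regions of interest.

    Pixels within ``radius + dilation`` of a unit's center carry that
    unit's index; 0 elsewhere.  Where discs overlap, the contested pixel
    goes to the nearest center.
    """
    h, w = shape
    labels = np.zeros((h, w), dtype=np.int32)
    best = np.full((h, w), np.inf)
    rows, cols = np.mgrid[0:h, 0:w]
    for u in layout.units:
        r = u.radius + dilation
        d = np.hypot(rows - u.center[0], cols - u.center[1])
        take = (d <= r) & (d < best)
        labels[take] = u.unit_index
        best[take] = d[take]
    return labels


def overlaps(layout: PlateLayout, dilation: float = 0.0) -> set[int]:
    """Unit indices whose dilated discs overlap another unit's disc."""
    flagged: set[int] = set()
    us = layout.units
    for i in range(len(us)):
        for j in range(i + 1, len(us)):
            d = np.hypot(
                us[i].center[0] - us[j].center[0],
                us[i].center[1] - us[j].center[1],
            )
            if d < us[i].radius + us[j].radius + 2 * dilation:
                flagged.add(us[i].unit_index)
                flagged.add(us[j].unit_index)
    return flagged
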