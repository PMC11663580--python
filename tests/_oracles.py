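"""Independent brute-force oracles used only by the tests.

These deliberately use different algorithms from the package:
ray-casting parity (Möller–Trumbore) instead of winding numbers for
containment, Eberly's region-based point-triangle distance instead of
barycentric clamping, per-pixel Python loops instead of vectorized
binning/counting, and O(n^3) agglomeration instead of scipy linkage.
"""

from __future__ import annotations

import numpy as np

_RAY_DIR = np.array([0.5773502691896258, 0.33219280948873623, 0.7459623468168807])
_RAY_DIR2 = np.array([0.123456789, 0.987654321, 0.4142135623730951])


def ray_crossings(point: np.ndarray, points: np.ndarray, facets: np.ndarray,
                  direction: np.ndarray = _RAY_DIR) -> int:
    """Count ray-facet crossings (Möller–Trumbore, t > 0)."""
    n = 0
    eps = 1e-12
    for f in facets:
        v0, v1, v2 = points[f[0]], points[f[1]], points[f[2]]
        e1, e2 = v1 - v0, v2 - v0
        h = np.cross(direction, e2)
        a = e1 @ h
        if abs(a) < eps:
            continue
        s = point - v0
        u = (s @ h) / a
        if u < 0 or u > 1:
            continue
        q = np.cross(s, e1)
        v = (direction @ q) / a
        if v < 0 or u + v > 1:
            continue
        t = (e2 @ q) / a
        if t > eps:
            n += 1
    return n


def contains_ray(point: np.ndarray, points: np.ndarray, facets: np.ndarray) -> bool:
    """Inside iff an odd number of crossings (union of watertight
    components).  Falls back to a second ray direction on grazing hits."""
    c1 = ray_crossings(point, points, facets, _RAY_DIR)
    c2 = ray_crossings(point, points, facets, _RAY_DIR2)
    if c1 % 2 == c2 % 2:
        return c1 % 2 == 1
    c3 = ray_crossings(
        point, points, facets, np.array([0.9061798459, 0.1234567, 0.40207])
    )
    return c3 % 2 == 1


def point_triangle_distance_eberly(p: np.ndarray, tri: np.ndarray) -> float:
    """Eberly's region-based exact point-to-triangle distance."""
    b, e0, e1 = tri[0], tri[1] - tri[0], tri[2] - tri[0]
    d = b - p
    a00, a01, a11 = e0 @ e0, e0 @ e1, e1 @ e1
    b0, b1 = d @ e0, d @ e1
    c = d @ d
    det = max(a00 * a11 - a01 * a01, 1e-300)
    s, t = a01 * b1 - a11 * b0, a01 * b0 - a00 * b1

    if s + t <= det:
        if s < 0:
            if t < 0:  # region 4
                if b0 < 0:
                    t = 0.0
                    s = 1.0 if -b0 >= a00 else -b0 / a00
                else:
                    s = 0.0
                    if b1 >= 0:
                        t = 0.0
                    elif -b1 >= a11:
                        t = 1.0
                    else:
                        t = -b1 / a11
            else:  # region 3
                s = 0.0
                if b1 >= 0:
                    t = 0.0
                elif -b1 >= a11:
                    t = 1.0
                else:
                    t = -b1 / a11
        elif t < 0:  # region 5
            t = 0.0
            if b0 >= 0:
                s = 0.0
            elif -b0 >= a00:
                s = 1.0
            else:
                s = -b0 / a00
        else:  # region 0
            s /= det
            t /= det
    else:
        if s < 0:  # region 2
            tmp0, tmp1 = a01 + b0, a11 + b1
            if tmp1 > tmp0:
                numer = tmp1 - tmp0
                denom = a00 - 2 * a01 + a11
                s = 1.0 if numer >= denom else numer / denom
                t = 1.0 - s
            else:
                s = 0.0
                if tmp1 <= 0:
                    t = 1.0
                elif b1 >= 0:
                    t = 0.0
                else:
                    t = -b1 / a11
        elif t < 0:  # region 6
            tmp0, tmp1 = a01 + b1, a00 + b0
            if tmp1 > tmp0:
                numer = tmp1 - tmp0
                denom = a00 - 2 * a01 + a11
                t = 1.0 if numer >= denom else numer / denom
                s = 1.0 - t
            else:
                t = 0.0
                if tmp1 <= 0:
                    s = 1.0
                elif b0 >= 0:
                    s = 0.0
                else:
                    s = -b0 / a00
        else:  # region 1
            numer = a11 + b1 - a01 - b0
            if numer <= 0:
                s = 0.0
            else:
                denom = a00 - 2 * a01 + a11
                s = 1.0 if numer >= denom else numer / denom
            t = 1.0 - s
    closest = b + s * e0 + t * e1
    return float(np.linalg.norm(closest - p))


def distance_brute(p: np.ndarray, points: np.ndarray, facets: np.ndarray) -> float:
    return min(
        point_triangle_distance_eberly(p, points[f]) for f in facets
    )


def bin_colors_brute(colors: np.ndarray, bin_size: float) -> dict:
    """Per-pixel Python-loop Lab binning: index triple -> count."""
    counts: dict = {}
    for c in colors:
        key = tuple(int(np.floor(v / bin_size)) for v in c)
        counts[key] = counts.get(key, 0) + 1
    return counts


def single_linkage_brute(centers: np.ndarray, cut: float) -> list[set]:
    """O(n^3) agglomerative single linkage with a distance cut; returns
    clusters as sets of point indices."""
    clusters = [{i} for i in range(len(centers))]
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = min(
                    np.linalg.norm(centers[a] - centers[b])
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if d < best[0]:
                    best = (d, i, j)
        if best[0] > cut:
            break
        _, i, j = best
        clusters[i] |= clusters[j]
        del clusters[j]
    return clusters


def srgb_to_lab_textbook(rgb8: tuple) -> tuple:
    """Stepwise textbook sRGB (D65) -> XYZ -> CIELAB for one 8-bit color."""
    def expand(u: float) -> float:
        return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4

    r, g, b = (expand(v / 255.0) for v in rgb8)
    # classic published sRGB (Rec. 709 primaries) linear-RGB -> XYZ matrix
    m = np.array(
        [
            [0.412453, 0.357580, 0.180423],
            [0.212671, 0.715160, 0.072169],
            [0.019334, 0.119193, 0.950227],
        ]
    )
    x, y, z = m @ np.array([r, g, b])
    xn, yn, zn = 0.95047, 1.0, 1.08883  # D65, 2 degree observer

    def f(t: float) -> float:
        d = 6.0 / 29.0
        return t ** (1.0 / 3.0) if t > d**3 else t / (3 * d * d) + 4.0 / 29.0

    fx, fy, fz = f(x / xn), f(y / yn), f(z / zn)
    return 116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz)
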