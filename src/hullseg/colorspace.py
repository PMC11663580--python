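"""CIELAB conversion, color distance, and color-space voxelization.

Segmentation operates in CIELAB (L*a*b*) because Euclidean distance there
(ΔE) is approximately proportional to perceived color difference, which makes
a single distance threshold meaningful across the whole gamut.  Images are
converted once, then pixel colors are down-sampled into cubic "voxels"
(bins of side ``bin_size`` ΔE units) so that dense color clusters can be
inspected and used as candidate hull vertices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "LabImage",
    "VoxelGrid",
    "srgb_to_lab",
    "lab_to_srgb",
    "delta_e",
    "voxelize",
    "filter_voxels",
]


@dataclass
class LabImage:
    """Per-pixel CIELAB coordinates with an optional validity mask.

    Attributes
    ----------
    lab : (H, W, 3) float array of L, a, b per pixel.
    valid : (H, W) bool array; False marks pixels excluded upstream
        (background masking).  Excluded pixels contribute nothing to
        voxelization or segmentation.
    """

    lab: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lab = np.asarray(self.lab, dtype=float)
        if self.lab.ndim != 3 or self.lab.shape[2] != 3:
            raise ValueError("lab must have shape (H, W, 3)")
        if self.valid is None:
            self.valid = np.ones(self.lab.shape[:2], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.lab.shape[:2]:
                raise ValueError("validity mask dimensions must match image")

    @property
    def height(self) -> int:
        return self.lab.shape[0]

    @property
    def width(self) -> int:
        return self.lab.shape[1]

    def valid_colors(self) -> np.ndarray:
        """(N, 3) Lab colors of the valid pixels, row-major order."""
        return self.lab[self.valid]


@dataclass
class VoxelGrid:
    """Down-sampled color occupancy: binned Lab coordinates with counts.

    ``bins`` maps an integer index triple (floor(L/s), floor(a/s),
    floor(b/s)) to ``(center, count)`` where ``center`` is the geometric
    center of the cubic bin and ``count`` the number of contributing pixels.
    """

    bin_size: float
    bins: dict[tuple[int, int, int], tuple[np.ndarray, int]] = field(
        default_factory=dict
    )

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def total_count(self) -> int:
        return sum(c for _, c in self.bins.values())

    def centers(self) -> np.ndarray:
        """(N, 3) array of voxel center colors, sorted by bin index."""
        if not self.bins:
            return np.empty((0, 3))
        return np.array([self.bins[k][0] for k in sorted(self.bins)])

    def counts(self) -> np.ndarray:
        if not self.bins:
            return np.empty((0,), dtype=int)
        return np.array([self.bins[k][1] for k in sorted(self.bins)])


def srgb_to_lab(image: np.ndarray, illuminant: str = "D65") -> LabImage:
    """Convert an 8-bit sRGB raster to CIELAB (D65, 2° observer by default).

    The standard chain is applied: sRGB gamma expansion to linear RGB, the
    linear map to XYZ, then the CIELAB transform relative to the chosen
    white point.  16-bit input is accepted with a warning and rescaled.

    Parameters
    ----------
    image : (H, W, 3) uint8 (or uint16) sRGB array.
    illuminant : white-point id understood by the colorimetry backend
        ("D65", "D50", ...).

    Returns
    -------
    LabImage with the same spatial shape and an all-valid mask.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected a 3-channel image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint16:
        warnings.warn("16-bit input rescaled to [0, 1]", stacklevel=2)
        rgb = arr.astype(float) / 65535.0
    elif arr.dtype == np.uint8:
        rgb = arr.astype(float) / 255.0
    else:
        rgb = arr.astype(float)
        if rgb.max() > 1.0:
            rgb = rgb / 255.0
    lab = _skcolor.rgb2lab(rgb, illuminant=illuminant, observer="2")
    return LabImage(lab=lab)


def lab_to_srgb(lab: np.ndarray, illuminant: str = "D65") -> np.ndarray:
    """Inverse conversion to 8-bit sRGB (clipping out-of-gamut values)."""
    arr = np.asarray(lab, dtype=float)
    rgb = _skcolor.lab2rgb(arr, illuminant=illuminant, observer="2")
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def delta_e(c1, c2) -> np.ndarray | float:
    """Euclidean CIELAB distance (ΔE) between two colors or color arrays.

    Broadcasts over leading dimensions; the last axis must hold (L, a, b).
    """
    a = np.asarray(c1, dtype=float)
    b = np.asarray(c2, dtype=float)
    d = np.sqrt(np.sum((a - b) ** 2, axis=-1))
    return float(d) if d.ndim == 0 else d


def voxelize(lab: LabImage, bin_size: float = 1.0) -> VoxelGrid:
    """Down-sample valid pixel colors into cubic Lab bins.

    Each valid pixel is assigned to exactly one bin by floor division of
    each Lab axis by ``bin_size``; total counts are conserved.  The
    representative color of a bin is its geometric center.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    colors = lab.valid_colors()
    grid = VoxelGrid(bin_size=bin_size)
    if colors.size == 0:
        return grid
    idx = np.floor(colors / bin_size).astype(np.int64)
    uniq, counts = np.unique(idx, axis=0, return_counts=True)
    for key, count in zip(uniq, counts):
        center = (key + 0.5) * bin_size
        grid.bins[tuple(int(k) for k in key)] = (center, int(count))
    return grid


def filter_voxels(grid: VoxelGrid, min_pixels: int) -> VoxelGrid:
    """Retain only voxels representing at least ``min_pixels`` pixels.

    Filtering suppresses sparse colors (sensor noise, rare transitions) so
    the surviving voxels trace the dense clusters a hull should cover.
    ``min_pixels=0`` is the identity.
    """
    if min_pixels < 0:
        raise ValueError("min_pixels must be >= 0")
    out = VoxelGrid(bin_size=grid.bin_size)
    out.bins = {k: v for k, v in grid.bins.items() if v[1] >= min_pixels}
    return out
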