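"""Whole-image segmentation against a color hull, mask post-processing,
and mask agreement scoring.

Segmentation is purely pixel-wise: each pixel's Lab color is classified
against the hull (inside, or within ``delta`` ΔE of the surface).  No
neighborhood, texture, or shape information is used, which keeps the method
fast and morphology-agnostic.  Hole filling and small-object removal are
optional morphological clean-up steps applied afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .colorspace import LabImage
from .hull import FacetMesh, HullSpec, classify

__all__ = [
    "SegmentationParams",
    "segment",
    "fill_holes",
    "remove_small",
    "postprocess",
    "dice",
    "overlay",
]


@dataclass
class SegmentationParams:
    """Post-processing thresholds in pixels.

    fill_area : enclosed background holes smaller than this become
        foreground (0 disables).
    remove_area : foreground objects smaller than this are dropped
        (0 disables).  Useful for debris and materials that interfere
        with imaging (e.g. mesh over macroalgal discs).
    """

    fill_area: int = 0
    remove_area: int = 0

    def __post_init__(self) -> None:
        if self.fill_area < 0 or self.remove_area < 0:
            raise ValueError("fill_area and remove_area must be >= 0")


def segment(
    lab: LabImage, spec: HullSpec, mesh: FacetMesh | None = None
) -> np.ndarray:
    """Classify every valid pixel against the hull; returns a bool mask.

    Pixels excluded by the image validity mask are always background.
    Unique colors are classified once and broadcast to their member
    pixels; the result is exactly the naive per-pixel classification
    because the color -> verdict map is deterministic.
    """
    if mesh is None:
        mesh = spec.build()
    out = np.zeros(lab.lab.shape[:2], dtype=bool)
    valid = lab.valid
    if not valid.any():
        return out
    colors = lab.lab[valid]
    uniq, inverse = np.unique(colors, axis=0, return_inverse=True)
    verdict = np.asarray(classify(uniq, spec, mesh))
    out[valid] = verdict[inverse]
    return out


def fill_holes(mask: np.ndarray, fill_area: int) -> np.ndarray:
    """Fill enclosed background holes smaller than ``fill_area`` pixels.

    A hole is a 4-connected background component that does not touch the
    image border.  ``fill_area=0`` is the identity.
    """
    if fill_area < 0:
        raise ValueError("fill_area must be >= 0")
    mask = np.asarray(mask).astype(bool)
    if fill_area == 0:
        return mask.copy()
    # 4-connectivity for background (dual of 8-connected foreground)
    bg_labels, n = ndimage.label(~mask, structure=_CROSS)
    if n == 0:
        return mask.copy()
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touches_border = np.zeros(n + 1, dtype=bool)
    touches_border[np.unique(bg_labels[border & ~mask])] = True
    sizes = np.bincount(bg_labels.ravel(), minlength=n + 1)
    fill = ~touches_border & (sizes < fill_area)
    fill[0] = False
    return mask | fill[bg_labels]


def remove_small(mask: np.ndarray, remove_area: int) -> np.ndarray:
    """Drop 8-connected foreground objects smaller than ``remove_area``."""
    if remove_area < 0:
        raise ValueError("remove_area must be >= 0")
    mask = np.asarray(mask).astype(bool)
    if remove_area == 0:
        return mask.copy()
    labels, n = ndimage.label(mask, structure=_SQUARE)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    keep = sizes >= remove_area
    keep[0] = False
    return keep[labels]


def postprocess(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Apply removal then hole filling (removal first so debris cannot
    seal holes shut before they are measured)."""
    out = remove_small(mask, params.remove_area)
    return fill_holes(out, params.fill_area)


_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
_SQUARE = ndimage.generate_binary_structure(2, 2)  # 8-connectivity


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) between masks.

    Both masks empty is defined as perfect agreement (1.0).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask dimensions differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def overlay(
    image: np.ndarray,
    mask: np.ndarray,
    color: tuple[int, int, int] = (255, 0, 255),
) -> np.ndarray:
    """Draw the segmentation boundary on a copy of the source image.

    The boundary is the set of foreground pixels 8-adjacent to background.
    Pure debug side-channel; never feeds back into analysis.
    """
    img = np.asarray(image).copy()
    mask = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(mask, structure=_SQUARE, border_value=0)
    edge = mask & ~eroded
    img[edge] = color
    return img
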