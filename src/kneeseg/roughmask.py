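"""Rough per-bone trabecular masks from the level-set bright phase.

The bright phase contains trabecular marrow of both bones plus infrapatellar
fat.  A morphological opening with a 5-mm spherical element (erosion removes
thin bridges and small fat structures), a 26-connectivity component search
keeping the two largest components, and a dilation with the same element
yield separate rough femur and tibia masks.

Erosion/dilation by a metric ball are computed through the exact Euclidean
distance transform (equivalent to the explicit structuring element, but much
faster for large radii).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .types import BoneMask

log = logging.getLogger(__name__)

#: 26-connectivity structuring element for the component search
CONN26 = np.ones((3, 3, 3), dtype=bool)


def spherical_element(radius_mm: float, spacing_mm) -> np.ndarray:
    """Binary ball: voxel offsets whose physical norm is <= radius_mm.

    Symmetric under axis reflection; anisotropic spacing flattens the element
    along coarse axes.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    spacing = np.asarray(spacing_mm, dtype=float)
    half = np.floor(radius_mm / spacing).astype(int)
    grids = np.meshgrid(*[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)],
                        indexing="ij")
    dist2 = sum(g**2 for g in grids)
    return dist2 <= radius_mm**2


def erode_ball(mask: np.ndarray, radius_mm: float, spacing_mm) -> np.ndarray:
    """Erosion by the metric ball via the exact EDT: a voxel survives iff all
    voxels within radius_mm are foreground, i.e. its distance to the
    background exceeds radius_mm."""
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    d = ndimage.distance_transform_edt(mask, sampling=spacing_mm)
    return d > radius_mm


def dilate_ball(mask: np.ndarray, radius_mm: float, spacing_mm) -> np.ndarray:
    """Dilation by the metric ball via the exact EDT of the complement."""
    if mask.all():
        return np.ones_like(mask, dtype=bool)
    d = ndimage.distance_transform_edt(~mask, sampling=spacing_mm)
    return d <= radius_mm


def isolate_bones(
    bright_mask: np.ndarray,
    spacing_mm,
    radius_mm: float = 5.0,
    superior_is_low_index: bool = True,
) -> tuple[BoneMask, BoneMask]:
    """Split the bright-phase mask into rough femur and tibia masks.

    Erode with the 5-mm ball, keep the two largest 26-connected components,
    dilate each with the same ball.  The component whose centroid lies more
    superior along axis 0 is the femur.  Voxels claimed by both dilated
    components go to the one with the nearer centroid.
    """
    eroded = erode_ball(np.asarray(bright_mask, dtype=bool), radius_mm, spacing_mm)
    labeled, n = ndimage.label(eroded, structure=CONN26)
    if n < 2:
        raise ValueError(
            f"expected at least two connected components after erosion, found {n}"
        )
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:2] + 1
    comps = [labeled == k for k in keep]
    centroids = [np.array(ndimage.center_of_mass(c)) for c in comps]

    dilated = [dilate_ball(c, radius_mm, spacing_mm) for c in comps]
    overlap = dilated[0] & dilated[1]
    if overlap.any():
        log.info("dilated bone masks overlap in %d voxels; splitting by centroid distance",
                 int(overlap.sum()))
        idx = np.argwhere(overlap)
        sp = np.asarray(spacing_mm, dtype=float)
        d0 = np.linalg.norm((idx - centroids[0]) * sp, axis=1)
        d1 = np.linalg.norm((idx - centroids[1]) * sp, axis=1)
        to_first = d0 <= d1
        dilated[0][tuple(idx[~to_first].T)] = False
        dilated[1][tuple(idx[to_first].T)] = False

    order = np.argsort([c[0] for c in centroids])
    if not superior_is_low_index:
        order = order[::-1]
    femur_i, tibia_i = order[0], order[1]
    spacing = tuple(float(s) for s in np.atleast_1d(spacing_mm) * np.ones(3))
    return (
        BoneMask(dilated[femur_i], "femur", spacing),
        BoneMask(dilated[tibia_i], "tibia", spacing),
    )
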