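"""Per-slice contour geometry: sub-voxel contours of the rough mask, outward
normals by local SVD, and intensity lines resampled along the normals.

For each transverse slice the rough trabecular mask boundary is extracted at
sub-voxel precision and resampled to uniform arclength.  At each contour
point, the local neighborhood (the point and its n neighbors per side,
wrapping around the closed contour) is mean-centered and decomposed by SVD;
the left singular vector of the larger singular value is the tangent, the
other the normal, whose sign is chosen to point away from the contour
centroid.  Sampling the bias-corrected volume along each normal from 15 mm
inward to 30 mm outward and stacking one row per contour point gives the
intensity-line 2D image (IL2DI), on which the boundary optimizations work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .types import PlanarContour, VoxelGrid

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

def _resample_closed(points: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample a closed polyline to uniform arclength steps (~spacing)."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(4, int(round(total / spacing)))
    t = np.linspace(0.0, total, n, endpoint=False)
    return np.column_stack([np.interp(t, s, closed[:, 0]), np.interp(t, s, closed[:, 1])])


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _smooth_closed(points: np.ndarray) -> np.ndarray:
    """One circular [1/4, 1/2, 1/4] pass: removes the half-voxel staircase
    of marching squares on binary masks."""
    return 0.5 * points + 0.25 * (np.roll(points, 1, axis=0) + np.roll(points, -1, axis=0))


def extract_slice_contours(mask_slice: np.ndarray, spacing_vox: float = 1.0) -> list[np.ndarray]:
    """Sub-voxel marching-squares contours of a 2D mask at level 0.5,
    resampled to uniform arclength, lightly smoothed, counterclockwise,
    largest first."""
    padded = np.pad(mask_slice.astype(float), 1)
    raw = measure.find_contours(padded, 0.5)
    out = []
    for c in raw:
        pts = c - 1.0  # undo padding
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        pts = _resample_closed(pts, spacing_vox)
        if len(pts) > 4:
            pts = _smooth_closed(pts)
        if _signed_area(pts) < 0:
            pts = pts[::-1]
        out.append(pts)
    out.sort(key=lambda p: -abs(_signed_area(p)))
    return out


def extract_contours(bone_mask: np.ndarray, spacing_vox: float = 1.0) -> list[PlanarContour]:
    """All per-slice contours of a 3D mask (one or more per non-empty slice)."""
    contours = []
    for z in range(bone_mask.shape[0]):
        if not bone_mask[z].any():
            continue
        for pts in extract_slice_contours(bone_mask[z], spacing_vox):
            contours.append(PlanarContour(z, pts))
    if not contours:
        log.warning("mask has no non-empty slices")
    return contours


# ---------------------------------------------------------------------------
# SVD normals
# ---------------------------------------------------------------------------

def svd_normal(
    points: np.ndarray, index: int, n_neighbors: int = 4, centroid: np.ndarray | None = None
) -> np.ndarray:
    """Outward unit normal at ``points[index]`` of a closed contour.

    Builds the 2 x (2 n_neighbors + 1) matrix of the point and its symmetric
    neighbors (wrapping), subtracts per-row means, and takes the left
    singular vectors: u1 (largest singular value) is the tangent, u2 the
    normal, flipped to point away from the contour centroid.
    """
    if n_neighbors < 2:
        raise ValueError("n_neighbors must be >= 2")
    n = len(points)
    idx = (np.arange(index - n_neighbors, index + n_neighbors + 1)) % n
    m = points[idx].T.astype(float)  # 2 x k
    m = m - m.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(m, full_matrices=True)
    if s[0] <= 1e-12:
        raise ValueError("degenerate contour neighborhood: zero spread")
    normal = u[:, 1]
    centroid = points.mean(axis=0) if centroid is None else centroid
    if np.dot(normal, points[index] - centroid) < 0:
        normal = -normal
    return normal


def contour_normals(points: np.ndarray, n_neighbors: int = 4) -> np.ndarray:
    """Outward unit normal at every point of a closed contour."""
    centroid = points.mean(axis=0)
    return np.array(
        [svd_normal(points, i, n_neighbors, centroid) for i in range(len(points))]
    )


# ---------------------------------------------------------------------------
# IL2DI
# ---------------------------------------------------------------------------

@dataclass
class IntensityLineImage:
    """Row-per-ray resampled intensity matrix with its geometric map back to
    in-slice coordinates.

    ``rows[r, c]`` is the volume sampled at
    ``base_mm[r] + (c - origin_column) * step_mm * normal_mm[r]``.
    """

    rows: np.ndarray  # (n_rays, n_samples)
    slice_index: int
    origin_column: int
    step_mm: float
    inward_mm: float
    outward_mm: float
    base_points: np.ndarray  # contour points, voxel units (n_rays, 2)
    normals: np.ndarray  # unit normals in mm space (n_rays, 2)
    spacing_mm: tuple[float, float]  # in-slice voxel size
    oob: np.ndarray  # (n_rays, n_samples) True where the sample left the volume

    @property
    def n_rays(self) -> int:
        return self.rows.shape[0]

    @property
    def samples_per_row(self) -> int:
        return self.rows.shape[1]

    def to_slice_coords(self, row: int, column: float) -> np.ndarray:
        """Map an IL2DI cell to in-slice voxel coordinates (sub-voxel)."""
        sp = np.asarray(self.spacing_mm)
        base_mm = self.base_points[row] * sp
        pos_mm = base_mm + (column - self.origin_column) * self.step_mm * self.normals[row]
        return pos_mm / sp

    def nearest_cell(self, point_vox: np.ndarray) -> tuple[int, float]:
        """Inverse map: the (row, column) whose ray passes nearest the point."""
        sp = np.asarray(self.spacing_mm)
        p = np.asarray(point_vox, dtype=float) * sp
        rel = p - self.base_points * sp
        t = np.einsum("ij,ij->i", rel, self.normals)
        perp = rel - t[:, None] * self.normals
        cols = self.origin_column + t / self.step_mm
        in_range = (cols >= 0) & (cols <= self.samples_per_row - 1)
        d = np.linalg.norm(perp, axis=1) + np.where(in_range, 0.0, np.inf)
        row = int(np.argmin(d))
        return row, float(np.clip(cols[row], 0, self.samples_per_row - 1))


def build_il2di(
    vol_corrected: VoxelGrid,
    contour: PlanarContour,
    n_neighbors: int = 4,
    inward_mm: float = 15.0,
    outward_mm: float = 30.0,
    step_mm: float | None = None,
) -> IntensityLineImage:
    """Sample the bias-corrected volume along the contour normals.

    One row per contour point; columns run from ``-inward_mm`` to
    ``+outward_mm`` in ``step_mm`` increments (default: the finest in-slice
    voxel size), linearly interpolated.  Out-of-bounds samples take the
    nearest in-bounds value and are flagged in ``oob``.
    """
    if step_mm is None:
        step_mm = float(min(vol_corrected.spacing_mm[1:]))
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    sp = np.asarray(vol_corrected.spacing_mm[1:], dtype=float)
    slice_data = np.asarray(vol_corrected.data[contour.slice_index], dtype=float)
    shape = np.asarray(slice_data.shape)

    pts_mm = contour.points * sp
    normals = contour_normals(pts_mm, n_neighbors)

    n_in = int(np.floor(inward_mm / step_mm))
    n_out = int(np.floor(outward_mm / step_mm))
    t = (np.arange(n_in + n_out + 1) - n_in) * step_mm  # mm offsets

    pos_mm = pts_mm[:, None, :] + t[None, :, None] * normals[:, None, :]
    pos_vox = pos_mm / sp  # (rays, samples, 2)
    oob = (
        (pos_vox[..., 0] < 0) | (pos_vox[..., 0] > shape[0] - 1)
        | (pos_vox[..., 1] < 0) | (pos_vox[..., 1] > shape[1] - 1)
    )
    base_in = (
        (contour.points[:, 0] >= 0) & (contour.points[:, 0] <= shape[0] - 1)
        & (contour.points[:, 1] >= 0) & (contour.points[:, 1] <= shape[1] - 1)
    )
    if not base_in.any():
        raise ValueError("contour lies entirely outside the volume")

    coords = pos_vox.reshape(-1, 2).T
    samples = ndimage.map_coordinates(slice_data, coords, order=1, mode="nearest")
    rows = samples.reshape(pos_vox.shape[:2])

    return IntensityLineImage(
        rows=rows,
        slice_index=contour.slice_index,
        origin_column=n_in,
        step_mm=float(step_mm),
        inward_mm=float(inward_mm),
        outward_mm=float(outward_mm),
        base_points=contour.points.copy(),
        normals=normals,
        spacing_mm=(float(sp[0]), float(sp[1])),
        oob=oob,
    )
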