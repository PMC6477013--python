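"""Core containers shared across the segmentation pipeline.

Axis convention: axis 0 is the slice (superior->inferior) axis; axes 1 and 2
are the in-slice (transverse) axes.  All physical quantities are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VoxelGrid:
    """A 3D scalar volume with physical voxel spacing.

    Parameters
    ----------
    data:
        3D array of intensities (arbitrary units).
    spacing_mm:
        Per-axis voxel size in mm, ordered like the array axes.
    origin_mm:
        Physical coordinate of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VoxelGrid requires a 3D array, got ndim={self.data.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def like(self, data: np.ndarray) -> "VoxelGrid":
        """New grid with the same geometry but different data."""
        return VoxelGrid(data, self.spacing_mm, self.origin_mm)


@dataclass
class BoneMask:
    """Single-bone binary mask with its anatomical label."""

    mask: np.ndarray
    label: str  # "femur" | "tibia"
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.label not in ("femur", "tibia"):
            raise ValueError(f"label must be 'femur' or 'tibia', got {self.label!r}")


@dataclass
class PlanarContour:
    """Ordered closed point sequence on one transverse slice.

    ``points`` are (row, col) in-slice voxel coordinates (sub-voxel precision),
    counterclockwise, without the duplicated closing point.
    """

    slice_index: int
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be an (n, 2) array")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class EvalReport:
    """Agreement scores between two segmentations."""

    dsc: float
    asd_mm: float
    per_slice_dsc: np.ndarray | None = None
    surface_point_counts: tuple[int, int] = (0, 0)

    def as_dict(self) -> dict:
        return {"dsc": self.dsc, "asd_mm": self.asd_mm,
                "n_surface_a": self.surface_point_counts[0],
                "n_surface_b": self.surface_point_counts[1]}
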