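"""Volume I/O: NIfTI via nibabel, MetaImage via SimpleITK.

Volumes are stored internally with axis 0 as the slice axis. NIfTI files are
written with a diagonal affine carrying the voxel spacing; reading recovers
spacing from the affine (NIfTI) or from the image header (MetaImage).
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .types import VoxelGrid

_NIFTI_EXT = (".nii", ".nii.gz")
_META_EXT = (".mha", ".mhd")


def _is_nifti(path: str) -> bool:
    return path.endswith(_NIFTI_EXT)


def read_volume(path: str) -> VoxelGrid:
    """Read a 3D scalar volume from NIfTI or MetaImage.

    Raises ``ValueError`` for unsupported formats or non-3D images, and if the
    header carries no spacing information.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _is_nifti(path):
        img = nib.load(path)
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={data.ndim}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
    elif path.endswith(_META_EXT):
        img = sitk.ReadImage(path)
        if img.GetDimension() != 3:
            raise ValueError(f"expected a 3D volume, got ndim={img.GetDimension()}")
        # SimpleITK returns arrays as (z, y, x); its spacing is (x, y, z).
        data = sitk.GetArrayFromImage(img)
        spacing = tuple(float(s) for s in img.GetSpacing()[::-1])
        origin = tuple(float(o) for o in img.GetOrigin()[::-1])
    else:
        raise ValueError(
            f"unsupported volume format for {path!r}; supported: "
            f"{', '.join(_NIFTI_EXT + _META_EXT)}"
        )
    if any(s <= 0 for s in spacing):
        raise ValueError(
            "volume header carries no positive spacing; supply --spacing explicitly"
        )
    return VoxelGrid(np.asarray(data, dtype=np.float64), spacing, origin)


def write_volume(path: str, grid: VoxelGrid, dtype=None) -> None:
    """Write a VoxelGrid to NIfTI or MetaImage, preserving spacing/origin."""
    data = grid.data if dtype is None else grid.data.astype(dtype)
    if _is_nifti(path):
        affine = np.diag(list(grid.spacing_mm) + [1.0])
        affine[:3, 3] = grid.origin_mm
        nib.save(nib.Nifti1Image(np.asarray(data), affine), path)
    elif path.endswith(_META_EXT):
        img = sitk.GetImageFromArray(np.asarray(data))
        img.SetSpacing(tuple(grid.spacing_mm[::-1]))
        img.SetOrigin(tuple(grid.origin_mm[::-1]))
        sitk.WriteImage(img, path)
    else:
        raise ValueError(f"unsupported output format for {path!r}")


def write_labels(path: str, labelmap: np.ndarray, spacing_mm, origin_mm=(0.0, 0.0, 0.0)) -> None:
    """Write an integer label map (uint8) as NIfTI/MetaImage."""
    grid = VoxelGrid(np.asarray(labelmap, dtype=np.uint8), spacing_mm, origin_mm)
    write_volume(path, grid, dtype=np.uint8)
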