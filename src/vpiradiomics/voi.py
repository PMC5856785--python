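"""Volume of interest: a 3D HU grid, an aligned binary mask and voxel spacing.

Grids are index-addressed ``(slice, row, column)``; axis 0 is the axial
(slice) axis.  ``spacing`` is millimetres per axis in the same order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateMaskError, ParameterError


@dataclass
class VOI:
    intensities: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    case_id: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensities.ndim != 3 or self.mask.ndim != 3:
            raise ParameterError("intensities and mask must be 3D arrays")
        if self.intensities.shape != self.mask.shape:
            raise ParameterError(
                f"shape mismatch: intensities {self.intensities.shape} "
                f"vs mask {self.mask.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError("spacing must be three positive values (mm)")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def masked_values(self) -> np.ndarray:
        """In-mask intensities as a flat array; raises on an empty mask."""
        if not self.mask.any():
            raise DegenerateMaskError("mask contains no voxels")
        return self.intensities[self.mask]

    def bounding_box(self) -> tuple[slice, slice, slice]:
        """Tight bounding box of the mask as slices per axis."""
        if not self.mask.any():
            raise DegenerateMaskError("mask contains no voxels")
        idx = np.nonzero(self.mask)
        return tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)


def read_voi(image_path: str | os.PathLike, mask_path: str | os.PathLike,
             case_id: str = "") -> VOI:
    """Read a volume/mask pair from NIfTI (.nii/.nii.gz) or NRRD files."""
    img, img_spacing = _read_volume(image_path)
    msk, _ = _read_volume(mask_path)
    return VOI(img, msk > 0.5, spacing=img_spacing,
               case_id=case_id or os.path.basename(str(image_path)))


def write_voi(voi: VOI, image_path: str | os.PathLike,
              mask_path: str | os.PathLike) -> None:
    """Write a volume/mask pair; format chosen from the file extension."""
    _write_volume(voi.intensities, voi.spacing, image_path)
    _write_volume(voi.mask.astype(np.uint8), voi.spacing, mask_path)


def _is_nifti(path: str) -> bool:
    return path.endswith(".nii") or path.endswith(".nii.gz")


def _read_volume(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = str(path)
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()[:3]
        # nibabel axes are (x, y, z); transpose to (slice, row, column)
        return np.transpose(data, (2, 1, 0)), (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    import SimpleITK as sitk

    img = sitk.ReadImage(path)
    data = sitk.GetArrayFromImage(img).astype(float)  # already (z, y, x)
    sx, sy, sz = img.GetSpacing()
    return data, (float(sz), float(sy), float(sx))


def _write_volume(data: np.ndarray, spacing: tuple[float, float, float],
                  path: str | os.PathLike) -> None:
    path = str(path)
    if _is_nifti(path):
        import nibabel as nib

        arr = np.transpose(np.asarray(data), (2, 1, 0))
        affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
        nib.save(nib.Nifti1Image(arr, affine), path)
        return
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.asarray(data))
    img.SetSpacing((spacing[2], spacing[1], spacing[0]))
    sitk.WriteImage(img, path)
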