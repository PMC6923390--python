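"""In-memory containers for 3D MR volumes and binary ROI masks.

Axes are voxel-indexed (x, y, z), 0-based; physical placement is carried as a
voxel spacing (mm) plus an origin so that a diagonal NIfTI affine can be
reconstructed on write.  All arrays are C-ordered numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["VolumeImage", "RoiMask", "save_nifti", "load_volume", "load_mask"]


@dataclass
class VolumeImage:
    """A 3D scalar grid with voxel spacing and placement.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar intensities (float64).
    spacing : tuple of float
        Voxel edge lengths in mm, all > 0.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0) in mm.
    modality : str
        ``"CE-T1"`` or ``"T2"`` (free-form for phantoms/tests).
    normalization : str
        ``"raw"`` or ``"zscored"``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = ""
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("VolumeImage expects a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, **changes) -> "VolumeImage":
        return replace(self, values=values, **changes)


@dataclass
class RoiMask:
    """A binary 3D grid aligned to a :class:`VolumeImage`."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError("RoiMask expects a 3D array")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be binary")
            arr = arr.astype(bool)
        self.values = np.ascontiguousarray(arr)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def is_empty(self) -> bool:
        return not self.values.any()


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_nifti(obj: VolumeImage | RoiMask, path) -> None:
    """Write a volume or mask as NIfTI-1 (masks as uint8)."""
    arr = obj.values
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, _affine(obj.spacing, obj.origin))
    nib.save(img, str(path))


def _load(path):
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return arr, spacing, origin


def load_volume(path, modality: str = "", normalization: str = "raw") -> VolumeImage:
    arr, spacing, origin = _load(path)
    return VolumeImage(arr.astype(np.float64), spacing, origin, modality, normalization)


def load_mask(path) -> RoiMask:
    arr, spacing, origin = _load(path)
    return RoiMask(arr > 0.5, spacing, origin)
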