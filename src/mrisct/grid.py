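"""Core image containers.

All volumes are 3D numpy arrays in ``(z, y, x)`` axis order with voxel
spacing in millimetres per axis.  Physical coordinates follow
``physical = origin + index * spacing`` with 0-based indices; every module
in the package inherits this convention.

Volumes are read and written as NIfTI through nibabel; on disk the array
is stored in ``(x, y, z)`` order (the NIfTI convention) with a diagonal
affine built from the spacing and origin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

#: Value semantics a volume may carry.
UNITS = ("HU", "MRI", "RED", "Gy", "label")


@dataclass
class ImageVolume:
    """A 3D scalar grid with spacing, origin and tagged value semantics.

    Parameters
    ----------
    data:
        3D array, axis order (z, y, x).
    spacing:
        Voxel spacing in mm per axis, ordered (z, y, x).
    origin:
        Physical position of voxel (0, 0, 0) in mm.
    unit:
        One of ``HU``, ``MRI``, ``RED``, ``Gy`` or ``label``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "HU"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "ImageVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map fractional (z, y, x) voxel indices to physical mm coordinates."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def physical_to_index(self, point: np.ndarray) -> np.ndarray:
        return (np.asarray(point) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def with_data(self, data: np.ndarray, unit: str | None = None) -> "ImageVolume":
        """A copy of this volume carrying ``data`` (and optionally a new unit)."""
        return replace(self, data=np.asarray(data), unit=unit or self.unit)

    def copy(self) -> "ImageVolume":
        return replace(self, data=self.data.copy())


@dataclass
class DixonSet:
    """The four co-registered channels of a Dixon acquisition.

    In-phase (IP), out-of-phase (OP), fat (F) and water (W) volumes; the
    acquisition physics imply IP = W + F and OP = |W - F| up to noise.
    """

    in_phase: ImageVolume
    out_phase: ImageVolume
    fat: ImageVolume
    water: ImageVolume

    def __post_init__(self) -> None:
        ref = self.in_phase
        for name in ("out_phase", "fat", "water"):
            vol = getattr(self, name)
            if not ref.same_grid(vol):
                raise ValueError(f"Dixon channel {name!r} is not on the in-phase grid")

    @property
    def channels(self) -> Mapping[str, ImageVolume]:
        return {
            "in_phase": self.in_phase,
            "out_phase": self.out_phase,
            "fat": self.fat,
            "water": self.water,
        }


def volume_to_nifti(vol: ImageVolume) -> nib.Nifti1Image:
    # (z, y, x) -> (x, y, z) for the NIfTI on-disk layout
    arr = np.ascontiguousarray(np.transpose(vol.data, (2, 1, 0)))
    affine = np.diag([vol.spacing[2], vol.spacing[1], vol.spacing[0], 1.0])
    affine[:3, 3] = [vol.origin[2], vol.origin[1], vol.origin[0]]
    img = nib.Nifti1Image(arr, affine)
    img.header.set_xyzt_units("mm")
    return img


def save_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii or .nii.gz); masks should be uint8."""
    nib.save(volume_to_nifti(vol), str(path))


def load_volume(path: str | Path, unit: str = "HU") -> ImageVolume:
    img = nib.load(str(path))
    arr = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = (float(img.affine[2, 3]), float(img.affine[1, 3]), float(img.affine[0, 3]))
    return ImageVolume(arr, spacing, origin, unit=unit)


def save_mask(mask: np.ndarray, like: ImageVolume, path: str | Path) -> None:
    save_volume(like.with_data(mask.astype(np.uint8), unit="label"), path)


def load_mask(path: str | Path) -> np.ndarray:
    return load_volume(path, unit="label").data.astype(bool)
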