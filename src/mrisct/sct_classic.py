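"""Density-assignment synthetic CT methods.

Two classic sCT strategies built on Dixon-MRI segmentation:

* **bulk density** — two classes: manually contoured bone and everything
  else in the body, each written as a single HU value derived from a
  relative electron density (bone RED 1.20, tissue RED 0.97 by default);
* **tissue class density** — three classes: bone, fat (thresholded from
  the fat-weighted Dixon channel) and muscle/viscera (body minus bone
  minus fat), at REDs 1.16 / 0.91 / 1.02 by default.

Bone is taken as an input mask (ground truth from the phantom, or a user
contour) since in practice it is outlined manually on the in-phase image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .density import DensityCalibration, red_to_hu
from .grid import DixonSet, ImageVolume

AIR_HU = -1000.0


@dataclass(frozen=True)
class BulkDensityValues:
    """Two-class override values (relative electron density, mass density g/cm^3)."""

    tissue_red: float = 0.97
    tissue_mass_density: float = 0.99
    bone_red: float = 1.20
    bone_mass_density: float = 1.25

    def __post_init__(self) -> None:
        if not self.bone_red > self.tissue_red > 0:
            raise ValueError("require bone_red > tissue_red > 0")


@dataclass(frozen=True)
class TissueClassValues:
    """Three-class override values (relative electron density, mass density g/cm^3)."""

    bone_red: float = 1.16
    muscle_red: float = 1.02
    fat_red: float = 0.91
    bone_mass_density: float = 1.20
    muscle_mass_density: float = 1.03
    fat_mass_density: float = 0.92

    def __post_init__(self) -> None:
        if not self.bone_red > self.muscle_red > self.fat_red:
            raise ValueError("require bone_red > muscle_red > fat_red")


def segment_body(
    mri_in_phase: ImageVolume,
    threshold: float | None = None,
    min_fraction: float = 0.05,
) -> np.ndarray:
    """Whole-body mask from the in-phase image by thresholding.

    The threshold defaults to an automatic bimodal (Otsu) split of the
    intensity histogram; the mask is the largest connected
    supra-threshold component with interior holes filled.
    """
    data = np.asarray(mri_in_phase.data, dtype=float)
    if np.ptp(data) == 0:
        raise ValueError("in-phase volume is constant; cannot threshold a body contour")
    if threshold is None:
        threshold = float(threshold_otsu(data))
    fg = data > threshold
    if not fg.any():
        raise ValueError("no voxel above the body threshold")
    comps, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(comps), comps, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    body = comps == largest
    if body.sum() < min_fraction * body.size:
        raise ValueError(
            f"largest component covers {body.sum() / body.size:.1%} of the grid "
            f"(< {min_fraction:.0%}); body segmentation failed"
        )
    # fill interior holes slice-wise and in 3D (bone/gas must stay inside)
    body = ndimage.binary_fill_holes(body)
    for z in range(body.shape[0]):
        body[z] = ndimage.binary_fill_holes(body[z])
    return body


def segment_fat(
    dixon: DixonSet, body: np.ndarray, ff_threshold: float = 0.5
) -> np.ndarray:
    """Fat mask from the Dixon fat/water pair inside the body.

    A voxel is fat when its fat fraction F/(F+W) exceeds ``ff_threshold``
    (default 0.5); voxels with F+W = 0 are excluded.
    """
    if not np.any(body):
        raise ValueError("body mask is empty")
    # negative intensities are noise artefacts; clamp so F/(F+W) stays in [0, 1]
    f = np.maximum(np.asarray(dixon.fat.data, dtype=float), 0.0)
    w = np.maximum(np.asarray(dixon.water.data, dtype=float), 0.0)
    total = f + w
    with np.errstate(divide="ignore", invalid="ignore"):
        ff = np.where(total > 0, f / np.where(total > 0, total, 1.0), 0.0)
    return body & (total > 0) & (ff > ff_threshold)


def _check_subset(inner: np.ndarray, outer: np.ndarray, name: str) -> None:
    n_out = int(np.sum(inner & ~outer))
    if n_out:
        raise ValueError(f"{name} mask has {n_out} voxel(s) outside the body mask")


def assign_bulk_density(
    body: np.ndarray,
    bone: np.ndarray,
    values: BulkDensityValues | None = None,
    cal: DensityCalibration | None = None,
    like: ImageVolume | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ImageVolume:
    """Two-class bulk density sCT: bone and soft tissue, air outside the body."""
    values = values or BulkDensityValues()
    cal = cal or DensityCalibration()
    _check_subset(bone, body, "bone")
    hu = np.full(body.shape, AIR_HU, dtype=float)
    hu[body] = red_to_hu(values.tissue_red, cal)
    hu[bone] = red_to_hu(values.bone_red, cal)
    if like is not None:
        return like.with_data(hu, unit="HU")
    return ImageVolume(hu, spacing, unit="HU")


def assign_tissue_class(
    body: np.ndarray,
    bone: np.ndarray,
    fat: np.ndarray,
    values: TissueClassValues | None = None,
    cal: DensityCalibration | None = None,
    like: ImageVolume | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ImageVolume:
    """Three-class sCT: bone > fat > muscle precedence, air outside the body.

    Muscle/viscera is the Boolean subtraction of fat and bone from the
    body contour; overlap voxels go to bone (the manual contour is
    authoritative), then fat.
    """
    values = values or TissueClassValues()
    cal = cal or DensityCalibration()
    _check_subset(bone, body, "bone")
    _check_subset(fat, body, "fat")
    hu = np.full(body.shape, AIR_HU, dtype=float)
    hu[body] = red_to_hu(values.muscle_red, cal)
    hu[fat & body] = red_to_hu(values.fat_red, cal)
    hu[bone & body] = red_to_hu(values.bone_red, cal)
    if like is not None:
        return like.with_data(hu, unit="HU")
    return ImageVolume(hu, spacing, unit="HU")
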