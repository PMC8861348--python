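"""Relative electron density (RED) <-> HU calibration and bowel-gas override.

Dose engines consume electron density relative to water, while synthetic
CTs are stored in Hounsfield units; a piecewise-linear calibration curve
converts between the two.  The default curve is a standard two-segment
shape anchored at air (-1000 HU, RED 0), water (0 HU, RED 1) and dense
bone (1500 HU, RED 1.85); a site-specific curve can be substituted from a
two-column CSV.

``override_bowel_gas`` replaces gas pockets in the bowel with the average
HU of the surrounding tissue, the standard preparation step before
comparing dose on image pairs whose gas distribution differs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grid import ImageVolume

DEFAULT_BREAKPOINTS: tuple[tuple[float, float], ...] = (
    (-1000.0, 0.0),
    (0.0, 1.0),
    (1500.0, 1.85),
)


@dataclass(frozen=True)
class DensityCalibration:
    """Piecewise-linear, invertible HU -> RED curve."""

    breakpoints: tuple[tuple[float, float], ...] = DEFAULT_BREAKPOINTS

    def __post_init__(self) -> None:
        pts = np.asarray(self.breakpoints, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ValueError("breakpoints must be >= 2 (HU, RED) pairs")
        if np.any(np.diff(pts[:, 0]) <= 0) or np.any(np.diff(pts[:, 1]) <= 0):
            raise ValueError("breakpoints must be strictly increasing in HU and RED")
        if not np.any(np.isclose(self.hu_to_red(0.0), 1.0, atol=1e-9)):
            raise ValueError("calibration must map 0 HU to RED 1.0")
        if pts[0, 0] > -1000 or pts[-1, 0] < 1500:
            raise ValueError("calibration must span at least [-1000, 1500] HU")

    @property
    def _hu(self) -> np.ndarray:
        return np.asarray(self.breakpoints, dtype=float)[:, 0]

    @property
    def _red(self) -> np.ndarray:
        return np.asarray(self.breakpoints, dtype=float)[:, 1]

    def hu_to_red(self, hu, strict: bool = False):
        hu = np.asarray(hu, dtype=float)
        _check_range(hu, self._hu, "HU", strict)
        out = np.interp(np.clip(hu, self._hu[0], self._hu[-1]), self._hu, self._red)
        return float(out) if out.ndim == 0 else out

    def red_to_hu(self, red, strict: bool = False):
        red = np.asarray(red, dtype=float)
        _check_range(red, self._red, "RED", strict)
        out = np.interp(np.clip(red, self._red[0], self._red[-1]), self._red, self._hu)
        return float(out) if out.ndim == 0 else out

    @classmethod
    def from_csv(cls, path: str | Path) -> "DensityCalibration":
        pts = np.loadtxt(path, delimiter=",", ndmin=2)
        return cls(tuple((float(h), float(r)) for h, r in pts))

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, np.asarray(self.breakpoints), delimiter=",", fmt="%.6g")


def _check_range(x: np.ndarray, grid: np.ndarray, name: str, strict: bool) -> None:
    n_out = int(np.sum((x < grid[0]) | (x > grid[-1])))
    if n_out:
        msg = f"{n_out} {name} value(s) outside calibrated range [{grid[0]}, {grid[-1]}]"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + "; clamping", stacklevel=3)


def red_to_hu(red, cal: DensityCalibration | None = None, strict: bool = False):
    """Convert RED values (scalar, array or ImageVolume) to HU."""
    cal = cal or DensityCalibration()
    if isinstance(red, ImageVolume):
        return red.with_data(cal.red_to_hu(red.data, strict), unit="HU")
    return cal.red_to_hu(red, strict)


def hu_to_red(hu, cal: DensityCalibration | None = None, strict: bool = False):
    """Convert HU values (scalar, array or ImageVolume) to RED."""
    cal = cal or DensityCalibration()
    if isinstance(hu, ImageVolume):
        return hu.with_data(cal.hu_to_red(hu.data, strict), unit="RED")
    return cal.hu_to_red(hu, strict)


def override_bowel_gas(
    volume: ImageVolume,
    body: np.ndarray,
    gas_threshold: float = -200.0,
    shell_radius: float = 10.0,
) -> tuple[ImageVolume, int]:
    """Replace in-body gas pockets by the mean HU of the surrounding tissue.

    Every connected component of in-body voxels below ``gas_threshold`` is
    replaced, as a unit, by the mean HU over the non-gas voxels within
    ``shell_radius`` mm of the component.  Returns the corrected volume
    and the number of voxels replaced; a second application replaces 0.
    """
    if not np.any(body):
        raise ValueError("body mask is empty")
    hu = np.asarray(volume.data, dtype=float).copy()
    gas = (hu < gas_threshold) & body
    if not gas.any():
        return volume.with_data(hu), 0

    components, n_comp = ndimage.label(gas)
    # spacing-aware spherical structuring element of the shell radius
    ranges = [np.arange(-int(np.ceil(shell_radius / s)), int(np.ceil(shell_radius / s)) + 1) * s
              for s in volume.spacing]
    Z, Y, X = np.meshgrid(*ranges, indexing="ij")
    ball = (Z**2 + Y**2 + X**2) <= shell_radius**2

    n_replaced = 0
    for comp_id in range(1, n_comp + 1):
        comp = components == comp_id
        shell = ndimage.binary_dilation(comp, structure=ball) & ~gas & body
        if not shell.any():
            raise ValueError(
                f"gas component {comp_id} has no tissue voxel within {shell_radius} mm"
            )
        hu[comp] = hu[shell].mean()
        n_replaced += int(comp.sum())
    return volume.with_data(hu), n_replaced
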