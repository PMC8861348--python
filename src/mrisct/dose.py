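"""Simplified multi-beam attenuation dose engine and DVH statistics.

This engine deliberately models only primary-photon attenuation: each of
``n_beams`` equally spaced coplanar beams (a VMAT-arc surrogate) deposits

    dose(x)  proportional to  exp(-mu_eff * WED(x))

inside its aperture, where WED is the water-equivalent (radiological)
depth, the line integral of relative electron density from the body
surface to x along the ray.  There is no scatter, build-up or
inverse-square term: the purpose is sensitivity of dose to HU/RED
differences along ray paths between a CT and a synthetic CT, not
clinical accuracy.

The beam sum is scaled once so the isocenter receives the prescription
dose on the reference (CT-derived) volume; the same frozen scale is
reused for the paired sCT run, mirroring a plan recalculated with
identical monitor units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import ImageVolume


@dataclass(frozen=True)
class BeamConfig:
    n_beams: int = 36
    isocenter: tuple[float, float, float] | None = None  # mm; None -> reference point
    aperture_margin: float = 10.0  # mm around the PTV beam's-eye projection
    mu_eff: float = 0.006  # effective attenuation per mm water-equivalent depth
    prescription_dose: float = 50.0  # Gy

    def __post_init__(self) -> None:
        if self.n_beams < 1:
            raise ValueError("n_beams must be >= 1")
        if self.mu_eff <= 0:
            raise ValueError("mu_eff must be positive")


@dataclass
class DoseReport:
    icru_point_dose: float  # Gy at the reference point
    dvh: dict[str, dict[str, float]] = field(default_factory=dict)  # structure -> metric -> value


def _beam_dose_axis_aligned(
    red: np.ndarray, aperture_zx: np.ndarray, spacing_y: float, mu: float
) -> np.ndarray:
    """Dose of one beam travelling along +y in the (rotated) grid frame.

    Radiological depth is the running midpoint line integral of RED along
    the ray; air outside the body carries RED ~ 0, so integration from
    the grid edge starts at the body surface.
    """
    cumulative = np.cumsum(red, axis=1) * spacing_y
    wed = cumulative - red * spacing_y / 2.0  # midpoint rule: depth to voxel centre
    dose = np.exp(-mu * wed)
    return dose * aperture_zx[:, None, :]


def _aperture_zx(ptv_rot: np.ndarray, margin_mm: float, spacing) -> np.ndarray:
    proj = ptv_rot.any(axis=1)
    if margin_mm <= 0:
        return proj.astype(float)
    rz = np.arange(-int(np.ceil(margin_mm / spacing[0])), int(np.ceil(margin_mm / spacing[0])) + 1)
    rx = np.arange(-int(np.ceil(margin_mm / spacing[2])), int(np.ceil(margin_mm / spacing[2])) + 1)
    Z, X = np.meshgrid(rz * spacing[0], rx * spacing[2], indexing="ij")
    disk = (Z**2 + X**2) <= margin_mm**2
    return ndimage.binary_dilation(proj, structure=disk).astype(float)


def sample_at_point(volume: ImageVolume, point_mm) -> float:
    """Trilinear sample of a volume at a physical (z, y, x) point."""
    idx = volume.physical_to_index(np.asarray(point_mm, dtype=float))
    return float(
        ndimage.map_coordinates(
            np.asarray(volume.data, dtype=float), np.asarray(idx).reshape(3, 1), order=1
        )[0]
    )


def calculate_dose(
    red: ImageVolume,
    body: np.ndarray,
    ptv: np.ndarray,
    beams: BeamConfig,
    reference_point=None,
    scale: float | None = None,
) -> tuple[ImageVolume, float]:
    """Dose grid (Gy) for an arc of equispaced coplanar beams.

    With ``scale=None`` the beam sum is normalized so the isocenter
    (``beams.isocenter`` or ``reference_point``) receives the
    prescription dose; pass the returned scale back in for the paired
    sCT calculation so both runs share identical beam weights.
    """
    if red.unit != "RED":
        raise ValueError("dose engine consumes relative electron density volumes")
    iso = beams.isocenter if beams.isocenter is not None else reference_point
    if iso is None:
        raise ValueError("an isocenter or reference point is required")
    iso_idx = red.physical_to_index(np.asarray(iso, dtype=float))
    if not all(0 <= i <= n - 1 for i, n in zip(iso_idx, red.shape)):
        raise ValueError("isocenter lies outside the grid")
    iso_vox = tuple(int(round(i)) for i in iso_idx)
    if not body[iso_vox]:
        raise ValueError("isocenter lies outside the body")

    red_arr = np.clip(np.asarray(red.data, dtype=float), 0.0, None)
    ptv_arr = np.asarray(ptv, dtype=float)
    angles = np.arange(beams.n_beams) * (360.0 / beams.n_beams)
    total = np.zeros(red.shape)
    for theta in angles:
        if theta % 360.0 == 0.0:
            red_rot, ptv_rot = red_arr, ptv_arr
        else:
            red_rot = ndimage.rotate(
                red_arr, theta, axes=(1, 2), reshape=False, order=1, mode="constant", cval=0.0
            )
            ptv_rot = ndimage.rotate(
                ptv_arr, theta, axes=(1, 2), reshape=False, order=1, mode="constant", cval=0.0
            )
        aperture = _aperture_zx(ptv_rot > 0.5, beams.aperture_margin, red.spacing)
        beam = _beam_dose_axis_aligned(red_rot, aperture, red.spacing[1], beams.mu_eff)
        if theta % 360.0 != 0.0:
            beam = ndimage.rotate(
                beam, -theta, axes=(1, 2), reshape=False, order=1, mode="constant", cval=0.0
            )
        total += beam

    dose = red.with_data(total, unit="Gy")
    if scale is None:
        at_iso = sample_at_point(dose, iso)
        if at_iso <= 0:
            raise ValueError("zero dose at the isocenter; aperture misses it")
        scale = beams.prescription_dose / at_iso
    out = dose.with_data(np.maximum(total * scale, 0.0))
    return out, float(scale)


def dose_at_rank(doses_desc: np.ndarray, x: float) -> float:
    """Dx by fractional-rank interpolation on descending-sorted voxel doses.

    ``Dx`` is the dose received by at least x% of the structure: linear
    interpolation at rank ``x * N / 100``; at an exact midpoint rank the
    lower-dose voxel is taken, so two equal halves at 40/60 Gy give
    D50 = 40 Gy.
    """
    n = doses_desc.size
    r = np.clip(x * n / 100.0, 0.0, n - 1.0)
    lo = int(np.floor(r))
    hi = int(np.ceil(r))
    f = r - lo
    return float((1 - f) * doses_desc[lo] + f * doses_desc[hi])


def dvh_metrics(
    dose: ImageVolume,
    mask: np.ndarray,
    prescription: float,
    d_levels=(98.0, 95.0, 50.0, 2.0),
    v_levels=(95.0,),
) -> dict[str, float]:
    """Dx (Gy) and Vy (%) metrics for one structure.

    Dx = dose received by at least x% of the structure volume;
    Vy = % of the structure receiving at least y% of the prescription.
    """
    if not np.any(mask):
        raise ValueError("structure mask is empty")
    doses = np.sort(np.asarray(dose.data, dtype=float)[np.asarray(mask, dtype=bool)])[::-1]
    out: dict[str, float] = {}
    for x in d_levels:
        out[f"D{x:g}"] = dose_at_rank(doses, x)
    for y in v_levels:
        out[f"V{y:g}"] = float(100.0 * np.mean(doses >= y / 100.0 * prescription))
    return out


def dose_report(
    dose: ImageVolume,
    structures: dict[str, np.ndarray],
    reference_point,
    prescription: float,
) -> DoseReport:
    """ICRU-point dose plus DVH metrics for every named structure."""
    report = DoseReport(icru_point_dose=sample_at_point(dose, reference_point))
    for name, mask in structures.items():
        report.dvh[name] = dvh_metrics(dose, mask, prescription)
    return report


def percent_dose_difference(d_sct, d_ct, min_reference: float = 0.0):
    """(DsCT - DCT) / DCT * 100%, elementwise; sign preserved.

    For metric dictionaries, returns one %DD per metric plus the
    combined average under the key ``combined_avg``.  Metrics whose
    reference value is below ``min_reference`` (structures essentially
    unirradiated, where a ratio is meaningless) are skipped.
    """
    if isinstance(d_sct, dict):
        out = {}
        for key, ct_val in d_ct.items():
            if abs(ct_val) < min_reference or ct_val == 0:
                continue
            out[key] = percent_dose_difference(d_sct[key], ct_val)
        out["combined_avg"] = (
            float(np.mean([v for k, v in out.items() if k != "combined_avg"]))
            if len(out)
            else float("nan")
        )
        return out
    if d_ct == 0:
        raise ValueError("reference dose is zero; percentage difference undefined")
    return float((d_sct - d_ct) / d_ct * 100.0)
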