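"""Parametric pelvis phantoms: paired pseudo-CT + Dixon pseudo-MRI with ground truth.

The generator builds a pelvis-like cross-section from analytic geometry
(elliptic body with a subcutaneous fat rind, femoral and sacral bone with
cortical shell and marrow core, bladder, rectal tube with optional gas
pocket, a planning target volume) and renders

* a CT volume in Hounsfield units with per-tissue-class means and SDs,
* the four Dixon MRI channels (fat bright in the fat image, muscle and
  viscera bright in the water image, IP = W + F, OP = |W - F| before
  noise), shaded by a smooth multiplicative bias field,
* the ground-truth tissue label map and structure masks.

Anatomy is parametric rather than image-derived so that ground truth is
exact and cohorts with controlled inter-subject variability can be drawn
for atlas experiments.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .grid import DixonSet, ImageVolume

# tissue-class label codes
BG, FAT, MUSCLE, BONE_CORTICAL, BONE_MARROW, BLADDER, GAS = 0, 1, 2, 3, 4, 5, 6

CLASS_NAMES = {
    BG: "background",
    FAT: "fat",
    MUSCLE: "muscle",
    BONE_CORTICAL: "bone_cortical",
    BONE_MARROW: "bone_marrow",
    BLADDER: "bladder",
    GAS: "gas",
}

#: Textbook-typical HU means/SDs per tissue class (configuration, not claims).
DEFAULT_TISSUE_HU: dict[str, tuple[float, float]] = {
    "fat": (-100.0, 15.0),
    "muscle": (45.0, 15.0),
    "bone_cortical": (800.0, 60.0),
    "bone_marrow": (250.0, 50.0),
    "bladder": (15.0, 10.0),
    "gas": (-1000.0, 20.0),
}

#: Per-class (fat-signal, water-signal) means in arbitrary MRI units.
DEFAULT_MRI_INTENSITY: dict[str, tuple[float, float]] = {
    "fat": (900.0, 80.0),
    "muscle": (120.0, 700.0),
    "bone_cortical": (50.0, 50.0),
    "bone_marrow": (400.0, 520.0),
    "bladder": (30.0, 950.0),
    "gas": (5.0, 5.0),
}


def default_organ_geometry(sex_variant: str = "male") -> dict[str, dict[str, Any]]:
    """Per-structure geometric parameters in mm, centred on the grid centre.

    The female variant shifts the PTV from the rectum (anorectal target)
    to the uterocervical region and widens the body outline slightly.
    """
    geom = {
        "body": {"semiaxes_yx": (95.0, 115.0)},
        "fat_rind": {"thickness": 12.0},
        "femur_left": {"center_yx": (10.0, -62.0), "radius": 15.0, "cortex": 4.0},
        "femur_right": {"center_yx": (10.0, 62.0), "radius": 15.0, "cortex": 4.0},
        "sacrum": {"center_yx": (68.0, 0.0), "semiaxes_yx": (20.0, 30.0), "cortex": 3.0},
        "bladder": {"center_yx": (-40.0, 0.0), "semiaxes_zyx": (28.0, 24.0, 30.0)},
        "rectum": {"center_yx": (42.0, 0.0), "radius": 13.0, "wall": 4.0},
        "ptv": {"center_yx": (42.0, 0.0), "semiaxes_zyx": (45.0, 35.0, 35.0)},
    }
    if sex_variant == "female":
        geom["body"] = {"semiaxes_yx": (95.0, 120.0)}
        geom["ptv"] = {"center_yx": (10.0, 0.0), "semiaxes_zyx": (45.0, 38.0, 35.0)}
    return geom


def scaled_organ_geometry(factor: float, sex_variant: str = "male") -> dict:
    """Default geometry uniformly scaled (e.g. to fit smaller test grids)."""
    geom = default_organ_geometry(sex_variant)
    for params in geom.values():
        for key, val in params.items():
            params[key] = (
                tuple(v * factor for v in val) if isinstance(val, tuple) else val * factor
            )
    return geom


@dataclass
class PhantomSpec:
    """Full parametric description of one synthetic pelvis case."""

    grid_shape: tuple[int, int, int] = (48, 64, 64)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    sex_variant: str = "male"
    organ_geometry: dict[str, dict[str, Any]] | None = None
    tissue_hu: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_HU)
    )
    mri_intensity: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MRI_INTENSITY)
    )
    bias_field_amplitude: float = 0.2
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"ct": 1.0, "mri": 20.0}
    )
    gas_pocket: bool = False
    gas_size: float = 16.0
    prescription_dose: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.organ_geometry is None:
            self.organ_geometry = default_organ_geometry(self.sex_variant)
        if self.sex_variant not in ("male", "female"):
            raise ValueError(f"sex_variant must be male or female, got {self.sex_variant!r}")
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("grid_shape must be >= 16 voxels per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.tissue_hu["gas"][0] > -800:
            raise ValueError("gas HU mean must be <= -800")
        for name, (_, sd) in self.tissue_hu.items():
            if sd < 0:
                raise ValueError(f"negative HU SD for class {name!r}")


@dataclass
class PhantomCase:
    """Ground-truth bundle: CT, Dixon MRI, labels, masks, plan metadata."""

    ct: ImageVolume
    mri: DixonSet
    labels: ImageVolume
    masks: dict[str, np.ndarray]
    reference_point: tuple[float, float, float]
    prescription_dose: float
    spec: PhantomSpec | None = None

    def __post_init__(self) -> None:
        if not self.ct.same_grid(self.labels):
            raise ValueError("CT and label map are on different grids")
        body = self.masks["body"]
        for name, mask in self.masks.items():
            if mask.shape != body.shape:
                raise ValueError(f"mask {name!r} has mismatched shape")
            if name != "body" and np.any(mask & ~body):
                raise ValueError(f"mask {name!r} is not contained in the body mask")


def _physical_grids(shape, spacing):
    """Physical (z, y, x) mm coordinates relative to the grid centre."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _build_labels(spec: PhantomSpec):
    """Rasterize geometry into a label map and the named structure masks."""
    Z, Y, X = _physical_grids(spec.grid_shape, spec.spacing)
    geom = spec.organ_geometry

    by, bx = geom["body"]["semiaxes_yx"]
    half_y = (spec.grid_shape[1] - 1) / 2.0 * spec.spacing[1]
    half_x = (spec.grid_shape[2] - 1) / 2.0 * spec.spacing[2]
    if by > half_y or bx > half_x:
        raise ValueError("structure 'body' exceeds the grid extent")

    body = (Y / by) ** 2 + (X / bx) ** 2 <= 1.0
    rind = geom["fat_rind"]["thickness"]
    inner = (Y / max(by - rind, 1.0)) ** 2 + (X / max(bx - rind, 1.0)) ** 2 <= 1.0

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[body] = FAT
    labels[inner] = MUSCLE

    masks: dict[str, np.ndarray] = {"body": body}

    def _require_inside(name: str, mask: np.ndarray) -> None:
        if np.any(mask & ~body):
            raise ValueError(f"structure {name!r} exceeds the grid/body extent")

    # femoral bones: cortical annulus around a marrow core, cylinders along z
    femur = np.zeros_like(body)
    for side in ("femur_left", "femur_right"):
        cy, cx = geom[side]["center_yx"]
        r, cortex = geom[side]["radius"], geom[side]["cortex"]
        d2 = (Y - cy) ** 2 + (X - cx) ** 2
        outer = d2 <= r**2
        core = d2 <= max(r - cortex, 0.0) ** 2
        _require_inside(side, outer)
        labels[outer] = BONE_CORTICAL
        labels[core] = BONE_MARROW
        femur |= outer

    cy, cx = geom["sacrum"]["center_yx"]
    sy, sx = geom["sacrum"]["semiaxes_yx"]
    cortex = geom["sacrum"]["cortex"]
    e = ((Y - cy) / sy) ** 2 + ((X - cx) / sx) ** 2
    sacrum = e <= 1.0
    sacrum_core = ((Y - cy) / max(sy - cortex, 0.1)) ** 2 + (
        (X - cx) / max(sx - cortex, 0.1)
    ) ** 2 <= 1.0
    _require_inside("sacrum", sacrum)
    labels[sacrum] = BONE_CORTICAL
    labels[sacrum_core] = BONE_MARROW

    cy, cx = geom["bladder"]["center_yx"]
    sz, sy, sx = geom["bladder"]["semiaxes_zyx"]
    bladder = (Z / sz) ** 2 + ((Y - cy) / sy) ** 2 + ((X - cx) / sx) ** 2 <= 1.0
    _require_inside("bladder", bladder)
    labels[bladder] = BLADDER

    cy, cx = geom["rectum"]["center_yx"]
    r = geom["rectum"]["radius"]
    rectum = (Y - cy) ** 2 + (X - cx) ** 2 <= r**2
    _require_inside("rectum", rectum)
    labels[rectum] = MUSCLE  # wall and content render as soft tissue

    if spec.gas_pocket:
        gr = spec.gas_size / 2.0
        lumen_r = max(r - geom["rectum"]["wall"], 1.0)
        gas = (
            (Z / max(gr, 1.0)) ** 2
            + ((Y - cy) / min(gr, lumen_r)) ** 2
            + ((X - cx) / min(gr, lumen_r)) ** 2
        ) <= 1.0
        _require_inside("gas_pocket", gas)
        labels[gas] = GAS

    cy, cx = geom["ptv"]["center_yx"]
    sz, sy, sx = geom["ptv"]["semiaxes_zyx"]
    ptv = (Z / sz) ** 2 + ((Y - cy) / sy) ** 2 + ((X - cx) / sx) ** 2 <= 1.0
    _require_inside("ptv", ptv)

    bone = (labels == BONE_CORTICAL) | (labels == BONE_MARROW)
    masks.update(
        bone=bone,
        bladder=bladder,
        rectum=rectum,
        ptv=ptv,
        oar_bladder=bladder.copy(),
        oar_femur=femur,
    )
    reference_point_offset = (0.0, cy, cx)
    return labels, masks, reference_point_offset


def _bias_field(spec: PhantomSpec, rng: np.random.Generator, degree: int = 2) -> np.ndarray:
    """Exponential of a random low-order polynomial, amplitude-limited.

    Emulates the smooth multiplicative shading of real MRI coils; the
    log-field is a polynomial of total degree <= 3 scaled so the maximal
    fractional deviation equals ``bias_field_amplitude``.
    """
    if spec.bias_field_amplitude <= 0:
        return np.ones(spec.grid_shape)
    degree = min(int(degree), 3)
    shape = spec.grid_shape
    zn, yn, xn = [
        (np.arange(n) - (n - 1) / 2.0) / max((n - 1) / 2.0, 1.0) for n in shape
    ]
    Z, Y, X = np.meshgrid(zn, yn, xn, indexing="ij")
    poly = np.zeros(shape)
    for i in range(degree + 1):
        for j in range(degree + 1 - i):
            for k in range(degree + 1 - i - j):
                if i == j == k == 0:
                    continue
                poly += rng.normal() * (Z**i) * (Y**j) * (X**k)
    peak = np.abs(poly).max()
    if peak > 0:
        poly *= np.log1p(spec.bias_field_amplitude) / peak
    return np.exp(poly - poly.mean())


def generate_phantom(spec: PhantomSpec, seed: int | None = None) -> PhantomCase:
    """Render a seeded phantom case from its parametric description.

    Deterministic for fixed ``(spec, seed)``.  CT voxels are drawn
    per class as ``mean + noise_sd["ct"] * class_sd * N(0, 1)``; the Dixon
    channels satisfy IP = W + F and OP = |W - F| exactly before noise, and
    the bias field multiplies the MRI channels only.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    labels, masks, ref_offset = _build_labels(spec)

    n_class = max(CLASS_NAMES) + 1
    hu_mean = np.zeros(n_class)
    hu_sd = np.zeros(n_class)
    hu_mean[BG] = -1000.0
    fat_sig = np.zeros(n_class)
    water_sig = np.zeros(n_class)
    for code, name in CLASS_NAMES.items():
        if name == "background":
            continue
        hu_mean[code], hu_sd[code] = spec.tissue_hu[name]
        fat_sig[code], water_sig[code] = spec.mri_intensity[name]

    ct = hu_mean[labels] + spec.noise_sd["ct"] * hu_sd[labels] * rng.standard_normal(
        spec.grid_shape
    )
    ct[labels == BG] = -1000.0

    f0 = fat_sig[labels]
    w0 = water_sig[labels]
    bias = _bias_field(spec, rng)
    mri_noise = spec.noise_sd["mri"]
    channels = {}
    for name, base in (
        ("fat", f0),
        ("water", w0),
        ("in_phase", w0 + f0),
        ("out_phase", np.abs(w0 - f0)),
    ):
        img = bias * base
        if mri_noise > 0:
            img = img + mri_noise * rng.standard_normal(spec.grid_shape)
        channels[name] = ImageVolume(img, spec.spacing, unit="MRI")

    centre = tuple((n - 1) / 2.0 * s for n, s in zip(spec.grid_shape, spec.spacing))
    ref = tuple(c + o for c, o in zip(centre, ref_offset))
    return PhantomCase(
        ct=ImageVolume(ct, spec.spacing, unit="HU"),
        mri=DixonSet(**channels),
        labels=ImageVolume(labels, spec.spacing, unit="label"),
        masks=masks,
        reference_point=ref,
        prescription_dose=spec.prescription_dose,
        spec=spec,
    )


#: fractional jitter half-ranges used when drawing a cohort: a single
#: anatomy scale shared by every structure (so containment is preserved),
#: a small independent per-structure size jitter, and tissue-mean jitter.
COHORT_JITTER = {"anatomy_scale": 0.08, "structure_size": 0.03, "tissue_mean": 0.05}

_SIZE_KEYS = ("semiaxes_yx", "semiaxes_zyx", "radius", "thickness", "cortex", "wall")


def _jitter_spec(base: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    spec = copy.deepcopy(base)
    g = COHORT_JITTER["anatomy_scale"]
    s_extra = COHORT_JITTER["structure_size"]
    t = COHORT_JITTER["tissue_mean"]
    scale = 1 + rng.uniform(-g, g)
    for name, params in spec.organ_geometry.items():
        size_jit = 1 + rng.uniform(-s_extra, s_extra) if name != "body" else 1.0
        for key, val in params.items():
            factor = scale * (size_jit if key in _SIZE_KEYS else 1.0)
            if isinstance(val, tuple):
                params[key] = tuple(v * factor for v in val)
            else:
                params[key] = val * factor
    if t > 0:
        spec.tissue_hu = {
            name: (mean * (1 + rng.uniform(-t, t)), sd)
            for name, (mean, sd) in spec.tissue_hu.items()
        }
        # keep the invariant: gas stays below -800 HU
        gm, gs = spec.tissue_hu["gas"]
        spec.tissue_hu["gas"] = (min(gm, -800.0), gs)
    return spec


def generate_cohort(
    base: PhantomSpec, n: int, seed: int = 0, jitter: bool = True
) -> list[PhantomCase]:
    """Draw ``n`` internally consistent cases around a base anatomy.

    Organ geometry and tissue HU means are jittered uniformly within
    +/-8% and +/-5% respectively (set ``jitter=False`` for identical
    renderings); per-case seeds are spawned from the master seed.
    """
    if n < 2:
        raise ValueError("a cohort needs n >= 2 (atlas methods need at least one non-target pair)")
    seeds = np.random.SeedSequence(seed).spawn(n)
    cases = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        spec = _jitter_spec(base, rng) if jitter else copy.deepcopy(base)
        case_seed = int(rng.integers(0, 2**31 - 1))
        cases.append(generate_phantom(spec, seed=case_seed))
    return cases


def random_displacement_field(
    shape, spacing, amplitude: float, smoothness: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random displacement field (3, z, y, x) in mm, max norm = amplitude."""
    field = rng.standard_normal((3,) + tuple(shape))
    sigmas = [smoothness / s for s in spacing]
    for c in range(3):
        field[c] = ndimage.gaussian_filter(field[c], sigma=sigmas)
    norm = np.sqrt((field**2).sum(axis=0))
    peak = norm.max()
    if peak > 0 and amplitude >= 0:
        field *= amplitude / peak
    return field


def warp_phantom(
    case: PhantomCase, amplitude: float, smoothness: float = 30.0, seed: int = 0
) -> tuple[PhantomCase, np.ndarray, int]:
    """Warp every channel and mask by one smooth random displacement field.

    Returns ``(warped_case, field_mm, n_clamped)`` where ``field_mm`` has
    shape (3, z, y, x) and ``n_clamped`` counts voxels whose pull-back
    sample fell outside the grid and was clamped to the boundary.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    shape = case.ct.shape
    spacing = case.ct.spacing
    rng = np.random.default_rng(seed)
    field = random_displacement_field(shape, spacing, amplitude, smoothness, rng)
    if amplitude == 0:
        return (
            PhantomCase(
                ct=case.ct.copy(),
                mri=DixonSet(**{k: v.copy() for k, v in case.mri.channels.items()}),
                labels=case.labels.copy(),
                masks={k: v.copy() for k, v in case.masks.items()},
                reference_point=case.reference_point,
                prescription_dose=case.prescription_dose,
                spec=case.spec,
            ),
            field,
            0,
        )

    idx = np.indices(shape, dtype=float)
    coords = idx + field / np.asarray(spacing).reshape(3, 1, 1, 1)
    lo = np.zeros((3, 1, 1, 1))
    hi = (np.asarray(shape, dtype=float) - 1).reshape(3, 1, 1, 1)
    out_of_grid = np.any((coords < lo) | (coords > hi), axis=0)
    n_clamped = int(out_of_grid.sum())
    coords = np.clip(coords, lo, hi)

    def warp_img(data, order):
        out = ndimage.map_coordinates(
            np.asarray(data, dtype=float), coords, order=order, mode="nearest"
        )
        return out

    ct = case.ct.with_data(warp_img(case.ct.data, 1))
    mri = DixonSet(
        **{
            name: vol.with_data(warp_img(vol.data, 1))
            for name, vol in case.mri.channels.items()
        }
    )
    labels = case.labels.with_data(warp_img(case.labels.data, 0).astype(np.uint8))
    masks = {
        name: warp_img(mask.astype(float), 0).astype(bool)
        for name, mask in case.masks.items()
    }
    # the pull-back moves structures; re-anchor the plan point at the PTV centroid
    ptv_idx = np.argwhere(masks["ptv"])
    centroid = ptv_idx.mean(axis=0) * np.asarray(spacing) + np.asarray(case.ct.origin)
    warped = PhantomCase(
        ct=ct,
        mri=mri,
        labels=labels,
        masks=masks,
        reference_point=tuple(float(c) for c in centroid),
        prescription_dose=case.prescription_dose,
        spec=case.spec,
    )
    return warped, field, n_clamped
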