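"""Hybrid multi-atlas synthetic CT: registration + local weighted voting.

Each atlas MRI is aligned to the target MRI in two stages — a 6-DoF rigid
registration driven by body-mask overlap, then a structure-guided
deformable (demons) registration whose similarity image combines the
normalized MRI intensity with binary bone and bladder labels — and its CT
is propagated through the composed transform.  The propagated CTs are
fused by local weighted voting: each atlas voxel is weighted by

    w_i(x) = exp(-gain * d_i(x) / sigma^2)

where d_i is the mean squared intensity difference between the target and
atlas patches of a given 3D radius around x and sigma^2 is the in-body
target intensity variance.  The fused sCT is the weight-normalized sum of
the propagated CT values, a convex combination at every voxel.

A low-order polynomial bias-field correction homogenizes each MRI before
registration and patch comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .grid import ImageVolume

AIR_HU = -1000.0


@dataclass(frozen=True)
class LWVParams:
    patch_radius: int = 2  # voxels, isotropic 3D box half-width
    gain: float = 10.0
    intensity_metric: str = "mean-squared-difference"

    def __post_init__(self) -> None:
        if self.patch_radius < 0 or self.gain <= 0:
            raise ValueError("patch_radius must be >= 0 and gain > 0")
        if self.intensity_metric != "mean-squared-difference":
            raise ValueError("only the mean-squared-difference metric is implemented")


@dataclass
class AtlasPair:
    """One co-registered MRI/CT pair with its structure masks."""

    mri: ImageVolume  # single channel (in-phase) used for registration/fusion
    ct: ImageVolume
    masks: dict[str, np.ndarray]  # body required; bone/bladder used when present

    def __post_init__(self) -> None:
        if not self.mri.same_grid(self.ct):
            raise ValueError("atlas MRI and CT are not on the same grid")
        if "body" not in self.masks:
            raise ValueError("atlas pair needs a body mask")


@dataclass
class AtlasSet:
    pairs: list[AtlasPair]

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise ValueError("atlas set needs at least one pair")


@dataclass
class DeformationField:
    """Per-voxel displacement (mm) on the fixed (target) grid.

    ``displacement[:, z, y, x]`` is the (z, y, x) mm offset added to the
    physical position of target voxel (z, y, x) to reach the matching
    point in atlas space (a pull-back field for resampling the atlas).
    """

    displacement: np.ndarray  # (3, nz, ny, nx)
    spacing: tuple[float, float, float]
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement field contains non-finite values")

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.displacement**2).sum(axis=0))


# ---------------------------------------------------------------------------
# bias field correction


def correct_bias_field(
    mri: ImageVolume,
    body: np.ndarray,
    shrink: int = 2,
    fitting_levels: int = 3,
    iterations: int = 30,
    nonpositive_tolerance: float = 0.01,
    return_field: bool = False,
):
    """Divide out a smooth multiplicative intensity field (N4 estimate).

    The field is estimated with the N4 histogram-sharpening algorithm on
    a ``shrink``-downsampled copy (a coarse multi-level B-spline, so the
    estimate is low-frequency by construction), reconstructed at full
    resolution, normalized to mean 1.0 inside the body, and divided out.
    Deterministic for fixed inputs.
    """
    if not np.any(body):
        raise ValueError("body mask is empty")
    data = np.asarray(mri.data, dtype=float)
    body = np.asarray(body, dtype=bool)
    frac_nonpos = float(np.mean(data[body] <= 0))
    if frac_nonpos > nonpositive_tolerance:
        raise ValueError(
            f"{frac_nonpos:.1%} of in-body voxels are non-positive "
            f"(> {nonpositive_tolerance:.0%} tolerance); cannot fit a log-domain field"
        )
    if np.ptp(data[body]) == 0:
        # constant image: field is identically 1
        out = mri.with_data(data.copy())
        return (out, np.ones(mri.shape)) if return_field else out
    floor = float(np.percentile(data[body][data[body] > 0], 1)) * 1e-3
    img = _to_sitk(np.maximum(data, max(floor, 1e-9)), mri.spacing)
    mask = sitk.GetImageFromArray(body.astype(np.uint8))
    mask.CopyInformation(img)
    n4 = sitk.N4BiasFieldCorrectionImageFilter()
    n4.SetMaximumNumberOfIterations([int(iterations)] * int(fitting_levels))
    if shrink > 1:
        n4.Execute(sitk.Shrink(img, [shrink] * 3), sitk.Shrink(mask, [shrink] * 3))
    else:
        n4.Execute(img, mask)
    log_field = sitk.GetArrayFromImage(n4.GetLogBiasFieldAsImage(img))
    field = np.exp(log_field)
    field /= field[body].mean()
    corrected = mri.with_data(data / field)
    return (corrected, field) if return_field else corrected


# ---------------------------------------------------------------------------
# registration


def _to_sitk(data: np.ndarray, spacing) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.astype(np.float64)))
    img.SetSpacing((float(spacing[2]), float(spacing[1]), float(spacing[0])))
    return img


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return float(2.0 * np.sum(a & b) / denom) if denom else 1.0


def _normalize_intensity(data: np.ndarray, body: np.ndarray) -> np.ndarray:
    hi = np.percentile(data[body], 99.0)
    return np.clip(data / max(hi, 1e-9), 0.0, 1.2)


def _composite_image(mri_norm: np.ndarray, masks: dict, label_weight: float) -> np.ndarray:
    comp = mri_norm.copy()
    for name in ("bone", "bladder"):
        if name in masks:
            comp = comp + label_weight * masks[name].astype(float)
    return comp


def register_atlas_to_target(
    atlas_mri: ImageVolume,
    atlas_masks: dict[str, np.ndarray],
    target_mri: ImageVolume,
    target_masks: dict[str, np.ndarray],
    label_weight: float = 0.5,
    demons_iterations: tuple[int, ...] = (40, 20),
    demons_sigma: float = 1.5,
    rigid_only: bool = False,
) -> DeformationField:
    """Composed rigid (6 DoF) + demons deformable target->atlas transform.

    The rigid stage aligns the body masks; the deformable stage runs
    multi-resolution symmetric-forces demons on composite images that add
    ``label_weight``-scaled bone and bladder labels to the normalized
    intensity, so the named structures guide the alignment.  Raises if
    the rigid stage leaves body-mask Dice below 0.5.
    """
    spacing = target_mri.spacing
    t_body = target_masks["body"].astype(float)
    a_body = atlas_masks["body"].astype(float)
    sigma_mm = 2.0 * float(np.mean(spacing))
    fixed_mask = _to_sitk(ndimage.gaussian_filter(t_body, sigma_mm / np.asarray(spacing)), spacing)
    moving_mask = _to_sitk(ndimage.gaussian_filter(a_body, sigma_mm / np.asarray(spacing)), atlas_mri.spacing)

    initial = sitk.CenteredTransformInitializer(
        fixed_mask,
        moving_mask,
        sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.MOMENTS,
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=100
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(initial, inPlace=False)
    rigid = reg.Execute(fixed_mask, moving_mask)

    # body Dice after the rigid stage
    a_body_img = _to_sitk(a_body, atlas_mri.spacing)
    warped_body = sitk.GetArrayFromImage(
        sitk.Resample(a_body_img, fixed_mask, rigid, sitk.sitkNearestNeighbor, 0.0)
    )
    rigid_dice = _dice(warped_body > 0.5, t_body > 0.5)
    if rigid_dice < 0.5:
        raise RuntimeError(
            f"rigid stage failed: body Dice {rigid_dice:.3f} < 0.5 "
            f"(metric {reg.GetMetricValue():.4g}, {reg.GetOptimizerIteration()} iterations)"
        )

    t_norm = _normalize_intensity(np.asarray(target_mri.data, float), target_masks["body"].astype(bool))
    a_norm = _normalize_intensity(np.asarray(atlas_mri.data, float), atlas_masks["body"].astype(bool))
    fixed_comp = _to_sitk(_composite_image(t_norm, target_masks, label_weight), spacing)

    if rigid_only:
        total = rigid
    else:
        # resample atlas composite through the rigid transform, then demons
        moving_comp_native = _to_sitk(
            _composite_image(a_norm, atlas_masks, label_weight), atlas_mri.spacing
        )
        moving_comp = sitk.Resample(moving_comp_native, fixed_comp, rigid, sitk.sitkLinear, 0.0)
        disp = _multires_demons(fixed_comp, moving_comp, demons_iterations, demons_sigma)
        total = sitk.CompositeTransform(3)
        total.AddTransform(rigid)
        total.AddTransform(sitk.DisplacementFieldTransform(disp))

    field = _transform_to_field(total, target_mri)
    field.diagnostics.update(rigid_body_dice=rigid_dice)
    return field


def _multires_demons(fixed, moving, iterations, sigma) -> sitk.Image:
    levels = len(iterations)
    disp = None
    for level, iters in enumerate(iterations):
        shrink = 2 ** (levels - 1 - level)
        if shrink > 1:
            f = sitk.Shrink(fixed, [shrink] * 3)
            m = sitk.Shrink(moving, [shrink] * 3)
        else:
            f, m = fixed, moving
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(iters))
        demons.SetStandardDeviations(float(sigma))
        if disp is None:
            disp = demons.Execute(f, m)
        else:
            init = sitk.Resample(disp, f, sitk.Transform(), sitk.sitkLinear)
            init = sitk.Cast(init, sitk.sitkVectorFloat64)
            disp = demons.Execute(f, m, init)
    return sitk.Resample(disp, fixed, sitk.Transform(), sitk.sitkLinear)


def _transform_to_field(transform: sitk.Transform, target: ImageVolume) -> DeformationField:
    ref = _to_sitk(np.zeros(target.shape), target.spacing)
    filt = sitk.TransformToDisplacementFieldFilter()
    filt.SetReferenceImage(ref)
    disp_img = filt.Execute(transform)
    arr = sitk.GetArrayFromImage(disp_img)  # (z, y, x, [dx, dy, dz]) in mm
    displacement = np.stack([arr[..., 2], arr[..., 1], arr[..., 0]], axis=0)
    return DeformationField(displacement=displacement, spacing=target.spacing)


def apply_deformation(
    volume: ImageVolume, field: DeformationField, order: int = 1
) -> ImageVolume:
    """Pull-back resampling of ``volume`` through the field (order 0 for masks)."""
    idx = np.indices(volume.shape, dtype=float)
    coords = idx + field.displacement / np.asarray(volume.spacing).reshape(3, 1, 1, 1)
    out = ndimage.map_coordinates(
        np.asarray(volume.data, dtype=float), coords, order=order, mode="nearest"
    )
    return volume.with_data(out)


def warp_mask(mask: np.ndarray, field: DeformationField, spacing) -> np.ndarray:
    idx = np.indices(mask.shape, dtype=float)
    coords = idx + field.displacement / np.asarray(spacing).reshape(3, 1, 1, 1)
    return ndimage.map_coordinates(mask.astype(float), coords, order=0, mode="nearest") > 0.5


# ---------------------------------------------------------------------------
# local weighted voting


def local_weighted_voting(
    target_mri: ImageVolume,
    warped_pairs: list[tuple[ImageVolume, ImageVolume]],
    params: LWVParams | None = None,
    body: np.ndarray | None = None,
    return_weights: bool = False,
):
    """Patch-similarity weighted fusion of propagated atlas CTs.

    ``warped_pairs`` are (warped MRI, warped CT) tuples on the target
    grid.  Weights use exp(-gain * MSD / sigma^2) with sigma^2 the
    in-body target intensity variance; they are computed in a
    max-normalized form that cannot underflow to an all-zero sum, and the
    unweighted-mean fallback (counted in the report) guards degenerate
    voxels where it still would.
    """
    params = params or LWVParams()
    if not warped_pairs:
        raise ValueError("need at least one warped atlas pair")
    target = np.asarray(target_mri.data, dtype=float)
    if body is None:
        body = np.ones(target.shape, dtype=bool)
    sigma2 = float(np.var(target[body]))
    sigma2 = max(sigma2, 1e-12)
    size = 2 * params.patch_radius + 1

    msds = []
    cts = []
    for mri_w, ct_w in warped_pairs:
        diff2 = (target - np.asarray(mri_w.data, dtype=float)) ** 2
        msd = ndimage.uniform_filter(diff2, size=size, mode="nearest")
        msds.append(msd)
        cts.append(np.asarray(ct_w.data, dtype=float))
    msds = np.stack(msds)  # (n_atlas, z, y, x)
    cts = np.stack(cts)

    expo = -params.gain * msds / sigma2
    expo -= expo.max(axis=0, keepdims=True)  # exact ratio, no underflow of the best atlas
    weights = np.exp(expo)
    wsum = weights.sum(axis=0)
    fallback = ~np.isfinite(wsum) | (wsum <= 0)
    n_fallback = int(fallback.sum())
    if n_fallback:
        weights[:, fallback] = 1.0
        wsum = weights.sum(axis=0)
    weights /= wsum
    fused = (weights * cts).sum(axis=0)
    sct = target_mri.with_data(fused, unit="HU")
    info = {"n_fallback": n_fallback, "sigma2": sigma2}
    if return_weights:
        info["weights"] = weights
    return sct, info


# ---------------------------------------------------------------------------
# orchestration


def multi_atlas_sct(
    target_mri: ImageVolume,
    target_masks: dict[str, np.ndarray],
    atlas: AtlasSet,
    params: LWVParams | None = None,
    bias_correct: bool = True,
    rigid_only: bool = False,
) -> tuple[ImageVolume, dict]:
    """Full hybrid multi-atlas pipeline for one target case.

    Bias-corrects every MRI, registers each atlas pair to the target,
    propagates the atlas CT (linear) and masks (nearest) through the
    composed field, and fuses with local weighted voting.  Outside-body
    voxels are set to air.  Deterministic given its inputs.
    """
    params = params or LWVParams()
    body = target_masks["body"].astype(bool)
    t_mri = correct_bias_field(target_mri, body) if bias_correct else target_mri

    warped_pairs = []
    diagnostics = []
    for i, pair in enumerate(atlas.pairs):
        a_body = pair.masks["body"].astype(bool)
        a_mri = correct_bias_field(pair.mri, a_body) if bias_correct else pair.mri
        field = register_atlas_to_target(
            a_mri, pair.masks, t_mri, target_masks, rigid_only=rigid_only
        )
        mri_w = apply_deformation(a_mri, field, order=1)
        ct_w = apply_deformation(pair.ct, field, order=1)
        diag = dict(field.diagnostics)
        diag["pair_index"] = i
        diag["max_displacement_mm"] = float(field.magnitude().max())
        if "bone" in pair.masks and "bone" in target_masks:
            bone_w = warp_mask(pair.masks["bone"], field, target_mri.spacing)
            diag["bone_dice"] = _dice(bone_w, target_masks["bone"])
        diagnostics.append(diag)
        warped_pairs.append((mri_w, ct_w))

    sct, info = local_weighted_voting(t_mri, warped_pairs, params, body=body)
    out = sct.data.copy()
    out[~body] = AIR_HU
    report = {"pairs": diagnostics, "lwv": info}
    return sct.with_data(out), report
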