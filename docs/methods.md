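# Methods

This package re-creates, on synthetic data, a four-way comparison of
synthetic-CT (sCT) generation methods for MRI-only pelvic radiotherapy
planning, together with the validation machinery such comparisons use:
HU error statistics, a dose recalculation with frozen beam weights,
percentage dose differences at the reference point and over DVH
parameters, and 3D gamma analysis. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Pelvis phantoms

Clinical paired MRI/CT pelvis scans cannot be redistributed, so all
experiments run on parametric phantoms. Anatomy is analytic geometry on
a regular grid (axis order z, y, x; physical = origin + index x spacing):
an elliptic body outline with a subcutaneous fat rind, two femoral
cylinders and a sacral ellipse (cortical shell around a marrow core), an
ellipsoidal bladder, a rectal tube with an optional ellipsoidal gas
pocket, and an ellipsoidal PTV — centred on the rectum in the male
variant (anorectal target) and on the uterocervical region in the female
variant. Ground truth (label map, structure masks, reference point) is
exact by construction.

Rendering draws CT voxels per tissue class as `mean + noise_sd_ct * class_sd * N(0,1)`
with textbook-typical HU means (fat −100, muscle 45, cortical bone 800,
marrow 250, bladder 15, gas −1000); these are configuration, not claims
about any scanner. The Dixon channels are built from per-class fat/water
signal means with the acquisition identities IP = W + F and
OP = |W − F| holding exactly before noise; a multiplicative bias field
(exponential of a random polynomial of total degree ≤ 3, scaled so its
maximal fractional deviation equals `bias_field_amplitude`, default 0.2)
shades the MRI channels only; i.i.d. Gaussian noise (default SD 20
intensity units ≈ 2.4% of the muscle in-phase signal) is added last.
Marrow is given a mixed fat/water signature (fat fraction 0.43) so that
fat-fraction thresholding at 0.5 separates it from subcutaneous fat, as
the ground-truth labels do.

Cohorts jitter a base anatomy with one global scale factor (±8%,
shared by every structure so containment invariants survive), an
independent ±3% per-structure size jitter, and ±5% jitter on tissue HU
means. Seeds are spawned per case from the master seed.

What the phantoms do *not* emulate: organ texture, partial-volume
boundaries, susceptibility and motion artefacts, contrast agents, and
genuinely deformable inter-subject anatomy (differences are affine-ish
plus independent size changes). Passing tests therefore demonstrate
correctness of the algorithms and the expected *ordering* of the
methods, not clinical-scale error magnitudes.

## Density calibration

Dose calculation consumes relative electron density (RED). The default
HU↔RED curve is piecewise linear through (−1000 HU, 0.0),
(0 HU, 1.0), (1500 HU, 1.85) — the standard two-segment calibration
shape — and is invertible by construction; a site curve can be loaded
from CSV. Under this default, the bulk-density values map to
−30 HU (tissue, RED 0.97) and 352.9 HU (bone, RED 1.20).

The bowel-gas override replaces each connected component of in-body
voxels below −200 HU with the mean HU of the non-gas voxels within a
10 mm spherical shell of the component (per-component, not per-voxel,
for stability). The neighbourhood definition is our choice; −200 HU is
unambiguous for gas, and 10 mm captures local tissue context. The
operation is idempotent.

## Classic density-assignment methods

Body segmentation thresholds the in-phase image (automatic Otsu split by
default, manual threshold accepted), keeps the largest connected
component and fills interior holes. Fat segmentation thresholds the
Dixon fat fraction F/(F+W) at 0.5 (the threshold value is not dictated
by anything; 0.5 is the natural midpoint and bias-field free, since a
multiplicative field cancels in the ratio). Bone is an input mask — in
practice it is contoured manually on the in-phase image, so the pipeline
treats it as authoritative rather than automating it.

Bulk density writes two HU values (bone RED 1.20, remaining tissue RED
0.97); tissue-class writes three (bone 1.16, fat 0.91, muscle/viscera
1.02 = body minus bone minus fat), with precedence bone > fat > muscle
on overlaps. Outside the body is air (−1000 HU).

## Hybrid multi-atlas method

Each atlas MRI is aligned to the target MRI in two stages. The rigid
stage (6 DoF) maximizes body-mask agreement: mean-squares on
Gaussian-smoothed masks, moments initialization, full sampling, regular-
step gradient descent — deterministic, and it aborts if body Dice stays
below 0.5. The deformable stage runs multi-resolution symmetric-forces
demons (two levels, 40/20 iterations, smoothing sigma 1.5 voxels) on
composite images: normalized intensity (99th-percentile scaling) plus
0.5-weighted binary bone and bladder labels, so the named structures
guide the alignment. Atlas CTs propagate through the composed field with
linear interpolation, masks with nearest-neighbour.

Bias correction before registration and fusion uses the N4
histogram-sharpening algorithm on a 2x-shrunk copy (3 fitting levels, 30
iterations); the reconstructed field is normalized to mean 1 inside the
body before division, so corrected intensities keep their scale.

Fusion is local weighted voting: for voxel x and atlas i,
`w_i(x) = exp(-gain * d_i(x) / sigma^2)` where `d_i` is the mean squared
intensity difference over a cubic patch of radius 2 voxels and `sigma^2`
is the in-body target intensity variance; the sCT is the
weight-normalized sum of propagated CT values. The exponential-of-MSD
weight form, the radius (2) and the gain (10) are our documented
choices; the weights are computed in max-normalized form, which is
mathematically identical and cannot underflow to an all-zero sum (an
unweighted-mean fallback still guards degenerate voxels and is counted).
The output is a convex combination of the atlas CT values at every
voxel, and the gain → 0 limit is the unweighted mean.

## Conditional GAN

The generator is a U-Net: a 3×3 stride-1 convolution block, four 3×3
stride-2 down-sampling blocks doubling the filter count to the
bottleneck, four decoder levels (3×3 stride-2 transpose convolution,
skip concatenation, 3×3 fuse convolution), and a final 1×1 convolution
with tanh; batch norm + ReLU everywhere except the output block; dropout
0.5 after the bottleneck and after the widest decoder fuse block. The
discriminator scores (MRI, CT-or-sCT) two-channel pairs through five 3×3
stride-2 blocks with 8/16/32/64/128 filters and leaky-ReLU (slope 0.2),
a 1×1 128-filter block, and a fully connected sigmoid output. Losses:
binary cross entropy (adversarial) plus L1 to the target CT, both
weighted 1; Adam at learning rate 1e-4, batch size 10; weights
initialized N(0, 1e-4). The L1 loss is computed full-frame (whether it
should be body-masked is an open choice; full-frame also teaches the
background).

Two profiles exist: the full-resolution profile (320² slices, base 64
filters, 20 epochs) and the desk profile used by the tests and the
analysis scripts (64² slices, filters scaled by 1/4, 5 epochs), sized
for CPU-only runs. All layers, the backward passes and Adam are
implemented in numpy; gradients are verified against finite differences
in the test suite, and training is bit-reproducible for a fixed seed.

Preprocessing: background removed with the body mask, axial slices
resampled to the training matrix, MRI intensities standardized by
piecewise-linear mode alignment (0 → 0, in-body histogram mode → 0.5,
99.5th percentile → 1), and both channels affinely mapped to [−1, 1].
The CT mapping is symmetric about water ([−1250, 1250] HU) so the tanh
origin corresponds to water-equivalent tissue; it is inverted exactly at
prediction time, and outside-body voxels are set to −1000 HU. At the
desk training budget (tens of optimizer steps) the network learns the
soft-tissue mapping but not bone geometry; the smoke-run error bound in
the tests reflects that operating point, not converged training.

## Dose engine

The clinical treatment-planning system is replaced by a deliberately
simplified, deterministic engine whose only purpose is sensitivity of
dose to HU/RED differences along ray paths. `n_beams` (default 36)
equally spaced coplanar beams — a VMAT-arc surrogate — each deposit
`exp(-mu_eff * WED(x))` inside an aperture (PTV beam's-eye projection
dilated by 10 mm), where WED is the water-equivalent depth: the running
line integral of RED along the ray, computed by rotating the RED grid to
the beam axis (linear interpolation) and accumulating a midpoint-rule
cumulative sum at one-voxel steps. Air carries RED ≈ 0, so integration
from the grid edge starts at the body surface. There is no scatter,
build-up or inverse-square modelling. The beam sum is scaled once so the
isocenter (the plan reference point) receives the prescription dose on
the CT volume; the identical scale is reused for the paired sCT run,
mirroring a recalculation with identical monitor units. `mu_eff`
defaults to 0.006/mm, a megavoltage-beam effective attenuation.

The grid-rotation line integral replaces exact voxel-intersection
(Siddon) stepping: at one-voxel step length the quadrature error is
negligible against the engine's modelling simplifications (the
closed-form slab test agrees within 0.1%), and the rotation formulation
vectorizes over the whole volume.

DVH metrics: Dx (dose received by at least x% of the structure volume)
interpolates linearly at fractional rank x·N/100 of the
descending-sorted voxel doses; at an exact midpoint rank the lower-dose
voxel is taken, so two equal halves at 40/60 Gy give D50 = 40 Gy. Vy is
the volume fraction at or above y% of prescription. The reported set —
D98, D95, D50, D2, V95 — is our choice of "relevant parameters"; DVH
parameters whose reference value is below 1% of prescription (structures
essentially unirradiated by the scatter-free engine) are excluded from
percentage-difference averages, which would otherwise divide by ~0.

## Evaluation

HU error: ME = mean(sCT − CT) and MAE = mean|sCT − CT| over a region
mask with the superior and inferior 30 mm (rounded up to whole slices)
excluded; regions are whole body, bone, and soft tissue = body ∖ bone.

Gamma analysis: evaluated voxels are the body eroded by a spacing-aware
15 mm spherical element, restricted to reference doses at or above 10%
of the normalization dose (global: the maximum reference dose inside the
eroded body — the normalization convention is a documented choice).
γ(x) is the minimum over candidate points on a cubic lattice of step
dta/10 within a sphere of radius 3×dta of
√[(Δd/ΔD)² + (|x−p|²/dta²)], with the evaluated dose interpolated
trilinearly. The production search enumerates candidates in order of
increasing distance and retires a voxel once the distance term alone
exceeds its current best γ — an exact early exit, verified against
exhaustive brute-force enumeration in the tests (identical pass rates
and mean γ). The search exploits that evaluated voxels sit at integer
indices: each offset's trilinear weights are scalars, so candidate
evaluation reduces to eight gathers per integer cell and a matrix
product. Pass rate counts γ ≤ 1; the comparison is asymmetric and the
CT-plan dose is always the reference. A coarser profile (step dta/5,
radius 2×dta) is available for large cohort sweeps; the search radius
never affects the pass rate (beyond dta the distance term alone exceeds
1), only the saturation of failing voxels' γ values.

Mann–Whitney U: exact two-sided p by dynamic-programming enumeration of
the null distribution when min(n, m) ≤ 8 and there are no ties, else the
normal approximation with tie and continuity corrections; the path used
is reported. Cohort summaries report median and 25th/75th-percentile IQR
(linear interpolation) for percentage dose differences and mean ± 1
sample SD (0 for a single case) for gamma and HU-error metrics.

## Problem sizes

The analysis scripts and the acceptance script run a 4-case cohort on a
32×48×48 grid at 5 mm spacing with anatomy scaled to 85% (so cohort
jitter keeps every structure inside the grid), the desk cGAN profile,
and 2-fold cross-validated cGAN training; unit tests use grids from 5³
to 64×64×48. These sizes were chosen so the full comparison — including
leave-one-out atlas fusion and cGAN training — completes in minutes on a
single CPU while every algorithmic property (exactness, convexity,
ordering, reproducibility) is exercised at full fidelity.

## Known limitations

* The dose engine is not clinically meaningful; only differences between
  paired runs carry information.
* The cGAN desk profile is deliberately undertrained; its HU errors are
  dominated by unlearned bone geometry.
* The phantom's inter-subject variability is modest, which flatters the
  atlas method relative to clinical cohorts.
* Gamma mean values (not pass rates) depend mildly on the configured
  search radius for failing voxels.
* The registration engine assumes the target and atlas fields of view
  overlap substantially; it reports, but does not repair, poor rigid
  initialization.
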