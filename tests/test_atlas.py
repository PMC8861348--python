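"""Bias correction, structure-guided registration and label-fusion sCT."""

import numpy as np
import pytest

from mrisct.atlas import (
    AtlasPair,
    AtlasSet,
    LWVParams,
    correct_bias_field,
    local_weighted_voting,
    multi_atlas_sct,
    register_atlas_to_target,
    warp_mask,
)
import mrisct.phantom as ph
from mrisct.grid import ImageVolume
from mrisct.phantom import PhantomSpec, generate_phantom, warp_phantom
from mrisct.pipeline import ground_truth_masks

from conftest import dice


def reg_masks(case):
    m = ground_truth_masks(case)
    return {"body": m["body"], "bone": m["bone"], "bladder": m["bladder"]}


class TestBiasCorrection:
    def test_bias_free_input_nearly_unchanged(self):
        case = generate_phantom(PhantomSpec(bias_field_amplitude=0.0), seed=2)
        body = case.masks["body"]
        corr = correct_bias_field(case.mri.in_phase, body)
        rel = np.abs(corr.data - case.mri.in_phase.data)[body] / case.mri.in_phase.data[body]
        assert rel.max() < 0.02

    def test_known_bias_halves_uniform_region_cov(self):
        # low MRI noise isolates the shading component of the variation
        spec = PhantomSpec(bias_field_amplitude=0.2, noise_sd={"ct": 1.0, "mri": 4.0})
        case = generate_phantom(spec, seed=3)
        muscle = case.labels.data == ph.MUSCLE
        corr, field = correct_bias_field(case.mri.in_phase, case.masks["body"], return_field=True)
        cov = lambda v: v.std() / v.mean()
        assert cov(corr.data[muscle]) <= 0.5 * cov(case.mri.in_phase.data[muscle])
        assert field[case.masks["body"]].mean() == pytest.approx(1.0)

    def test_constant_image_unchanged(self, clean_case):
        const = clean_case.mri.in_phase.with_data(np.full(clean_case.ct.shape, 500.0))
        out = correct_bias_field(const, clean_case.masks["body"])
        assert np.allclose(out.data, 500.0)

    def test_nonpositive_intensities_rejected(self, default_case):
        bad = default_case.mri.in_phase.with_data(
            np.where(default_case.masks["body"], -1.0, 100.0)
        )
        with pytest.raises(ValueError, match="non-positive"):
            correct_bias_field(bad, default_case.masks["body"])


class TestRegistration:
    def test_identity_field_is_negligible(self, default_case):
        masks = reg_masks(default_case)
        field = register_atlas_to_target(
            default_case.mri.in_phase, masks, default_case.mri.in_phase, masks
        )
        max_disp_vox = field.magnitude().max() / min(default_case.ct.spacing)
        assert max_disp_vox < 1.0

    def test_recovers_known_rigid_shift(self):
        """10 mm translation along x, phantom sampled so it is a whole-voxel shift."""
        spec = PhantomSpec(grid_shape=(32, 64, 96), spacing=(4.0, 4.0, 2.5))
        case = generate_phantom(spec, seed=4)
        masks = reg_masks(case)
        shift_vox = 4  # 10 mm / 2.5 mm
        atlas_mri = case.mri.in_phase.with_data(np.roll(case.mri.in_phase.data, shift_vox, axis=2))
        atlas_masks = {k: np.roll(v, shift_vox, axis=2) for k, v in masks.items()}
        field = register_atlas_to_target(
            atlas_mri, atlas_masks, case.mri.in_phase, masks, rigid_only=True
        )
        centre = tuple(s // 2 for s in case.ct.shape)
        disp = field.displacement[:, centre[0], centre[1], centre[2]]
        assert abs(disp[2] - 10.0) < 1.0
        assert abs(disp[0]) < 1.0 and abs(disp[1]) < 1.0

    def test_recovers_smooth_warp_bone_overlap(self, default_case):
        warped, _, _ = warp_phantom(default_case, amplitude=5.0, smoothness=30.0, seed=5)
        t_masks = reg_masks(default_case)
        a_masks = reg_masks(warped)
        field = register_atlas_to_target(
            warped.mri.in_phase, a_masks, default_case.mri.in_phase, t_masks
        )
        bone_w = warp_mask(a_masks["bone"], field, default_case.ct.spacing)
        assert dice(bone_w, t_masks["bone"]) >= 0.90
        assert field.diagnostics["rigid_body_dice"] >= 0.5

    def test_disjoint_bodies_abort_with_diagnostic(self, default_case):
        masks = reg_masks(default_case)
        tiny = {k: np.zeros_like(v) for k, v in masks.items()}
        tiny["body"][:2, :2, :2] = True
        with pytest.raises(RuntimeError, match="Dice"):
            register_atlas_to_target(
                default_case.mri.in_phase, tiny, default_case.mri.in_phase, masks
            )


class TestLocalWeightedVoting:
    def test_single_atlas_returns_its_ct(self, default_case):
        body = default_case.masks["body"]
        for gain in (0.5, 50.0):
            sct, info = local_weighted_voting(
                default_case.mri.in_phase,
                [(default_case.mri.in_phase, default_case.ct)],
                LWVParams(gain=gain),
                body=body,
            )
            assert np.allclose(sct.data, default_case.ct.data)
            assert info["n_fallback"] == 0

    def test_identical_mris_average_cts(self, default_case):
        body = default_case.masks["body"]
        ct_b = default_case.ct.with_data(default_case.ct.data + 100.0)
        sct, _ = local_weighted_voting(
            default_case.mri.in_phase,
            [(default_case.mri.in_phase, default_case.ct), (default_case.mri.in_phase, ct_b)],
            body=body,
        )
        assert np.allclose(sct.data, default_case.ct.data + 50.0)

    def test_high_gain_selects_matching_atlas(self, default_case):
        body = default_case.masks["body"]
        mismatched_mri = default_case.mri.in_phase.with_data(
            default_case.mri.in_phase.data + 400.0
        )
        mismatched_ct = default_case.ct.with_data(default_case.ct.data + 500.0)
        sct, _ = local_weighted_voting(
            default_case.mri.in_phase,
            [
                (default_case.mri.in_phase, default_case.ct),
                (mismatched_mri, mismatched_ct),
            ],
            LWVParams(gain=100.0),
            body=body,
        )
        assert np.abs(sct.data - default_case.ct.data)[body].max() <= 1.0

    def test_output_is_convex_combination(self):
        rng = np.random.default_rng(0)
        shape = (8, 10, 10)
        target = np.random.default_rng(1).normal(500, 100, shape)
        t = ImageVolume(target, (4, 4, 4), unit="MRI")
        pairs = []
        for _ in range(4):
            mri = t.with_data(target + rng.normal(0, 50, shape))
            ct = t.with_data(rng.normal(0, 300, shape), unit="HU")
            pairs.append((mri, ct))
        sct, info = local_weighted_voting(t, pairs, LWVParams(gain=5.0))
        cts = np.stack([p[1].data for p in pairs])
        assert np.all(sct.data >= cts.min(axis=0) - 1e-9)
        assert np.all(sct.data <= cts.max(axis=0) + 1e-9)
        assert info["n_fallback"] == 0

    def test_zero_gain_limit_is_unweighted_mean(self, default_case):
        body = default_case.masks["body"]
        other = generate_phantom(PhantomSpec(sex_variant="female"), seed=9)
        pairs = [
            (default_case.mri.in_phase, default_case.ct),
            (other.mri.in_phase, other.ct),
        ]
        sct, _ = local_weighted_voting(
            default_case.mri.in_phase, pairs, LWVParams(gain=1e-9), body=body
        )
        mean_ct = (default_case.ct.data + other.ct.data) / 2
        assert np.allclose(sct.data, mean_ct, atol=1e-3)

    def test_empty_pairs_rejected(self, default_case):
        with pytest.raises(ValueError):
            local_weighted_voting(default_case.mri.in_phase, [])


class TestMultiAtlas:
    def test_atlas_containing_target_reproduces_ct(self, default_case):
        masks = reg_masks(default_case)
        pair = AtlasPair(
            mri=default_case.mri.in_phase,
            ct=default_case.ct,
            masks=ground_truth_masks(default_case),
        )
        sct, report = multi_atlas_sct(
            default_case.mri.in_phase, masks, AtlasSet([pair])
        )
        body = masks["body"]
        assert np.abs(sct.data - default_case.ct.data)[body].mean() <= 2.0
        assert len(report["pairs"]) == 1
        assert "rigid_body_dice" in report["pairs"][0]

    def test_report_has_one_diagnostic_per_pair(self, default_case):
        masks = reg_masks(default_case)
        others = [generate_phantom(PhantomSpec(), seed=s) for s in (21, 22)]
        pairs = [
            AtlasPair(mri=c.mri.in_phase, ct=c.ct, masks=ground_truth_masks(c))
            for c in others
        ]
        sct, report = multi_atlas_sct(
            default_case.mri.in_phase, masks, AtlasSet(pairs), rigid_only=True
        )
        assert len(report["pairs"]) == len(pairs)
        assert all("max_displacement_mm" in d for d in report["pairs"])

    def test_empty_atlas_rejected(self):
        with pytest.raises(ValueError):
            AtlasSet([])
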