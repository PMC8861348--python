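"""HU-error metrics, Mann-Whitney U and cohort summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu as scipy_mwu

from mrisct.evaluation import (
    end_slab_slices,
    hu_error,
    hu_error_by_region,
    mann_whitney_u,
    summarize_cohort,
)
from mrisct.grid import ImageVolume


def _vol(data):
    return ImageVolume(np.asarray(data, dtype=float), (5.0, 4.0, 4.0), unit="HU")


class TestHUError:
    def test_uniform_offset(self):
        ct = _vol(np.zeros((20, 8, 8)))
        sct = _vol(np.full((20, 8, 8), 20.0))
        rep = hu_error(sct, ct, np.ones((20, 8, 8), bool))
        assert rep.me == 20.0 and rep.mae == 20.0

    def test_alternating_offset_cancels_me_not_mae(self):
        ct = _vol(np.zeros((20, 8, 8)))
        delta = np.full((20, 8, 8), 20.0)
        delta[:, :, ::2] *= -1
        sct = _vol(delta)
        rep = hu_error(sct, ct, np.ones((20, 8, 8), bool))
        assert rep.me == 0.0 and rep.mae == 20.0

    def test_end_slab_exclusion_removes_exact_slice_count(self):
        # index-arithmetic oracle: ceil(30 / spacing_z) slices at each end
        assert end_slab_slices(20, 5.0, 30.0) == 6
        assert end_slab_slices(20, 4.0, 30.0) == 8
        assert end_slab_slices(20, 7.0, 30.0) == 5
        ct = _vol(np.zeros((20, 8, 8)))
        sct = ct.with_data(np.zeros((20, 8, 8)))
        sct.data[:6] = 500.0  # inside the excluded superior slab
        sct.data[-6:] = 500.0
        rep = hu_error(sct, ct, np.ones((20, 8, 8), bool), exclusion_mm=30.0)
        assert rep.me == 0.0
        assert rep.n_voxels == (20 - 12) * 64

    def test_me_additivity(self):
        rng = np.random.default_rng(0)
        ct = _vol(rng.normal(0, 100, (20, 8, 8)))
        sct = _vol(ct.data + rng.normal(0, 10, (20, 8, 8)))
        base = hu_error(sct, ct, np.ones((20, 8, 8), bool))
        shifted = hu_error(sct.with_data(sct.data + 7.0), ct, np.ones((20, 8, 8), bool))
        assert shifted.me == pytest.approx(base.me + 7.0)

    def test_region_empty_after_exclusion_rejected(self):
        ct = _vol(np.zeros((8, 8, 8)))
        region = np.zeros((8, 8, 8), bool)
        region[0] = True  # only in the excluded slab
        with pytest.raises(ValueError, match="empty"):
            hu_error(ct, ct, region)

    def test_soft_tissue_is_body_minus_bone(self, clean_case):
        reps = hu_error_by_region(
            clean_case.ct, clean_case.ct, clean_case.masks["body"], clean_case.masks["bone"]
        )
        assert reps["whole_body"].n_voxels == reps["bone"].n_voxels + reps["soft_tissue"].n_voxels
        for rep in reps.values():
            assert rep.mae >= abs(rep.me)


class TestMannWhitney:
    def test_separated_samples_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_exact_matches_full_enumeration(self):
        """Independent oracle: enumerate all C(7,3) rank placements."""
        a, b = [1.0, 4.0, 7.0], [2.0, 3.0, 5.0, 6.0]
        res = mann_whitney_u(a, b)
        u_obs = sum(x > y for x in a for y in b)
        n, m = len(a), len(b)
        us = [
            sum(c) - n * (n + 1) / 2
            for c in itertools.combinations(range(1, n + m + 1), n)
        ]
        p_le = np.mean([u <= u_obs for u in us])
        p_ge = np.mean([u >= u_obs for u in us])
        assert res.u == u_obs
        assert res.p_value == pytest.approx(min(1.0, 2 * min(p_le, p_ge)))

    def test_identical_samples_p_near_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value >= 0.99

    def test_u_complement_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(size=rng.integers(2, 12))
            assert mann_whitney_u(a, b).u + mann_whitney_u(b, a).u == len(a) * len(b)

    def test_normal_approximation_matches_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.4, 1, 30)
        res = mann_whitney_u(a, b)
        ref = scipy_mwu(a, b, alternative="two-sided", method="asymptotic")
        assert res.method == "normal_approx"
        assert res.u == ref.statistic
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def _tidy(values_by_method, metric="icru_pdd", group="all"):
    rows = []
    for method, values in values_by_method.items():
        for i, v in enumerate(values):
            rows.append(dict(case=i, group=group, method=method, metric=metric, value=v))
    return pd.DataFrame(rows)


class TestSummarizeCohort:
    def test_median_and_iqr(self):
        df = _tidy({"bulk": [1, 2, 3, 4, 5]})
        out = summarize_cohort(df)
        row = out.iloc[0]
        assert row["median"] == 3.0
        assert (row["iqr_low"], row["iqr_high"]) == (2.0, 4.0)
        assert row["summary"] == "median_iqr"

    def test_single_case_sd_zero(self):
        df = _tidy({"bulk": [2.5]}, metric="mae_whole_body")
        out = summarize_cohort(df)
        assert out.iloc[0]["sd"] == 0.0
        assert out.iloc[0]["summary"] == "mean_sd"

    def test_row_count_is_methods_times_metrics(self):
        df = pd.concat(
            [
                _tidy({"bulk": [1, 2], "atlas": [3, 4]}, metric="icru_pdd"),
                _tidy({"bulk": [1, 2], "atlas": [3, 4]}, metric="gamma_pass_3_2"),
            ]
        )
        out = summarize_cohort(df)
        assert len(out) == 2 * 2

    def test_unknown_group_rejected(self):
        df = _tidy({"bulk": [1, 2]}, group="male")
        with pytest.raises(ValueError, match="unknown group"):
            summarize_cohort(df, grouping="female")

    def test_group_filter(self):
        df = pd.concat([_tidy({"bulk": [1, 2]}, group="male"), _tidy({"bulk": [5, 6]}, group="female")])
        out = summarize_cohort(df, grouping="male")
        assert out.iloc[0]["median"] == 1.5
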