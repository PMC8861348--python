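"""cGAN configs, architecture conformance, preprocessing and training."""

import numpy as np
import pytest

from mrisct.cgan import (
    CganConfig,
    Discriminator,
    Generator,
    NormalizationMeta,
    generator_parameter_count,
    load_generator,
    mri_mode,
    predict_sct,
    preprocess_pair,
    save_generator,
    scale_ct,
    train_cgan,
    unscale_ct,
)
from mrisct import nn


def tiny_cfg(**kw):
    """Miniature profile for fast training-behaviour tests."""
    defaults = dict(matrix_size=32, base_filters=8, epochs=2, batch_size=4, seed=0)
    defaults.update(kw)
    return CganConfig(**defaults)


class TestConfig:
    def test_paper_profile_defaults(self):
        cfg = CganConfig()
        assert cfg.matrix_size == 320 and cfg.base_filters == 64
        assert cfg.learning_rate == 1e-4 and cfg.batch_size == 10 and cfg.epochs == 20

    def test_matrix_size_must_match_depth(self):
        with pytest.raises(ValueError, match="divisible"):
            CganConfig(matrix_size=100)

    def test_desk_profile(self):
        cfg = CganConfig.desk()
        assert cfg.matrix_size == 64 and cfg.base_filters == 16 and cfg.epochs == 5


class TestArchitecture:
    @pytest.mark.parametrize("base", [8, 16])
    def test_parameter_count_matches_closed_form(self, base):
        cfg = tiny_cfg(base_filters=base)
        assert Generator(cfg).n_parameters() == generator_parameter_count(base)

    def test_generator_output_shape_and_range(self):
        cfg = tiny_cfg()
        gen = Generator(cfg)
        x = np.random.default_rng(0).uniform(-1, 1, (2, 1, 32, 32))
        y = gen.forward(x, train=False)
        assert y.shape == x.shape
        assert np.all(np.abs(y) < 1.0)

    def test_discriminator_outputs_probability_per_pair(self):
        cfg = tiny_cfg()
        disc = Discriminator(cfg)
        x = np.random.default_rng(0).uniform(-1, 1, (3, 2, 32, 32))
        p = nn.sigmoid(disc.forward(x, train=False))
        assert p.shape == (3, 1)
        assert np.all((p > 0) & (p < 1))


class TestPreprocessing:
    def test_ct_scaling_round_trip(self, default_case):
        meta = NormalizationMeta()
        hu = np.clip(default_case.ct.data, meta.ct_lo, meta.ct_hi)
        assert np.abs(unscale_ct(scale_ct(hu, meta), meta) - hu).max() < 0.5

    def test_outputs_bounded(self, default_case):
        cfg = tiny_cfg()
        body = default_case.masks["body"]
        x, y, meta, info = preprocess_pair(
            default_case.ct, default_case.mri.in_phase, body, cfg
        )
        assert x.min() >= -1.0 and x.max() <= 1.0
        assert y.min() >= -1.0 and y.max() <= 1.0
        assert x.shape[2:] == (32, 32)
        assert len(info["kept_slices"]) + len(info["skipped_slices"]) == default_case.ct.shape[0]

    def test_global_intensity_scaling_is_normalized_away(self, default_case):
        """Mode alignment: a x2 brighter scan standardizes to the same peak."""
        meta = NormalizationMeta()
        body = default_case.masks["body"]
        mode1, hi1 = mri_mode(default_case.mri.in_phase.data, body, meta)
        mode2, hi2 = mri_mode(2.0 * default_case.mri.in_phase.data, body, meta)
        assert mode2 / mode1 == pytest.approx(2.0, rel=0.02)
        assert (mode2 / hi2) == pytest.approx(mode1 / hi1, rel=0.02)


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(0)
    x = rng.uniform(-1, 1, (12, 1, 32, 32))
    y = np.tanh(x * 0.5 + 0.2)
    return x, y


class TestTraining:
    def test_histories_are_seed_deterministic(self, toy_data):
        x, y = toy_data
        _, _, h1 = train_cgan(x, y, tiny_cfg())
        _, _, h2 = train_cgan(x, y, tiny_cfg())
        assert h1 == h2

    def test_history_structure_and_finiteness(self, toy_data):
        x, y = toy_data
        _, _, hist = train_cgan(x, y, tiny_cfg())
        assert [h["epoch"] for h in hist] == [0, 1]
        assert all(
            np.isfinite([h["g_adv"], h["g_l1"], h["d_loss"]]).all() for h in hist
        )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="batch_size"):
            train_cgan(np.zeros((2, 1, 32, 32)), np.zeros((2, 1, 32, 32)), tiny_cfg())


class TestPrediction:
    def test_round_trip_checkpoint_and_bit_identical_prediction(
        self, tmp_path, default_case
    ):
        cfg = tiny_cfg()
        body = default_case.masks["body"]
        x, y, meta, _ = preprocess_pair(default_case.ct, default_case.mri.in_phase, body, cfg)
        gen, _, _ = train_cgan(x, y, cfg)
        sct1 = predict_sct(gen, default_case.mri.in_phase, body, meta)
        sct2 = predict_sct(gen, default_case.mri.in_phase, body, meta)
        assert np.array_equal(sct1.data, sct2.data)

        save_generator(gen, meta, tmp_path / "model")
        gen2, meta2 = load_generator(tmp_path / "model")
        sct3 = predict_sct(gen2, default_case.mri.in_phase, body, meta2)
        assert np.array_equal(sct1.data, sct3.data)

    def test_output_grid_and_hu_range(self, default_case):
        cfg = tiny_cfg()
        body = default_case.masks["body"]
        x, y, meta, _ = preprocess_pair(default_case.ct, default_case.mri.in_phase, body, cfg)
        gen, _, _ = train_cgan(x, y, cfg)
        sct = predict_sct(gen, default_case.mri.in_phase, body, meta)
        assert sct.shape == default_case.mri.in_phase.shape
        assert sct.spacing == default_case.mri.in_phase.spacing
        assert np.all(sct.data[body] >= meta.ct_lo) and np.all(sct.data[body] <= meta.ct_hi)
        assert np.all(sct.data[~body] == -1000.0)

    def test_metadata_mismatch_rejected(self, default_case):
        gen = Generator(tiny_cfg())
        meta = NormalizationMeta(matrix_size=64)
        with pytest.raises(ValueError, match="matrix size"):
            predict_sct(gen, default_case.mri.in_phase, default_case.masks["body"], meta)
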