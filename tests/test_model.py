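"""Network architecture, losses, augmentation and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecglvh.errors import ConfigurationError, InvalidArgumentError
from ecglvh.model import (
    FineTuneConfig,
    ModelConfig,
    TrainConfig,
    augment_waveform,
    bce_with_logits_loss,
    build_fcn,
    count_parameters,
    fine_tune,
    log_cosh_loss,
    predict,
    train_model,
)
from ecglvh.nn import Dense


def closed_form_parameter_count(cfg: ModelConfig) -> int:
    """Independent per-layer arithmetic: conv in*k*out+out, BN 2*out,
    dense in*out+out."""
    total = 0
    in_ch = cfg.n_leads
    for filters, kernel in cfg.conv_blocks:
        total += in_ch * kernel * filters + filters  # conv
        total += 2 * filters  # batch-norm scale + shift
        in_ch = filters
    fc_in = cfg.conv_blocks[-1][0] + cfg.metadata_dim
    total += fc_in * cfg.fc_hidden + cfg.fc_hidden
    total += cfg.fc_hidden * 1 + 1
    return total


class TestArchitecture:
    def test_parameter_count_matches_closed_form(self):
        cfg = ModelConfig()
        assert count_parameters(build_fcn(cfg)) == closed_form_parameter_count(cfg)

    def test_metadata_ablation_isolates_concat_width(self):
        with_meta = count_parameters(build_fcn(ModelConfig(metadata_dim=15)))
        without = count_parameters(build_fcn(ModelConfig(metadata_dim=0)))
        assert with_meta - without == 15 * 128

    def test_single_dense_layer_count(self):
        layer = Dense(10, 1, np.random.default_rng(0))
        assert sum(v.size for v in layer.params.values()) == 11

    def test_gap_width_independent_of_length(self):
        for length in (96, 120, 160):
            model = build_fcn(ModelConfig(beat_length=length))
            x = np.zeros((2, 8, length), dtype=np.float32)
            pooled_dim = model.fc1.params["W"].shape[0] - model.config.metadata_dim
            assert pooled_dim == 128  # last block's filter count, any L
            out = model.forward(x, np.zeros((2, 15)), training=False)
            assert out.shape == (2,)

    def test_too_short_beat_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(beat_length=4)


class TestLogCosh:
    def test_zero_residual_is_zero(self):
        assert log_cosh_loss(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0

    def test_small_residual_quadratic_limit(self):
        loss = log_cosh_loss(np.array([1e-3]), np.array([0.0]))
        assert loss == pytest.approx(0.5e-6, rel=1e-4)

    def test_large_residual_linear_limit(self):
        loss = log_cosh_loss(np.array([10.0]), np.array([0.0]))
        assert loss == pytest.approx(9.30685, abs=1e-5)
        assert loss == pytest.approx(10.0 - np.log(2.0), rel=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            log_cosh_loss(np.zeros(3), np.zeros(4))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(x=st.floats(-60, 60, allow_nan=False))
    def test_even_and_monotone(self, x):
        f = lambda v: log_cosh_loss(np.array([v]), np.array([0.0]))
        assert f(x) == pytest.approx(f(-x), rel=1e-12, abs=1e-12)
        assert f(x * 1.5) >= f(x) - 1e-12

    def test_gradient_matches_tanh(self):
        loss, grad = log_cosh_loss(np.array([2.0, -1.0]), np.zeros(2),
                                   return_grad=True)
        np.testing.assert_allclose(grad, np.tanh([2.0, -1.0]) / 2)


class TestBce:
    def test_matches_direct_formula(self):
        z = np.array([-3.0, 0.0, 2.5])
        y = np.array([0.0, 1.0, 1.0])
        p = 1 / (1 + np.exp(-z))
        direct = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert bce_with_logits_loss(z, y) == pytest.approx(direct, rel=1e-9)


class TestAugmentation:
    def test_identity_configuration(self):
        cfg = FineTuneConfig(crop_max=0, noise_sd=0.0, amplitude_scale=(1.0, 1.0))
        x = np.random.default_rng(0).normal(size=(8, 120))
        np.testing.assert_array_equal(augment_waveform(x, cfg, np.random.default_rng(1)), x)

    def test_output_length_contract(self):
        cfg = FineTuneConfig()
        rng = np.random.default_rng(2)
        x = np.random.default_rng(0).normal(size=(8, 120))
        for _ in range(200):
            assert augment_waveform(x, cfg, rng).shape == (8, 120)

    def test_noise_sd_matches_configuration(self):
        cfg = FineTuneConfig(crop_max=0, noise_sd=0.005,
                             amplitude_scale=(1.0, 1.0))
        rng = np.random.default_rng(3)
        draws = np.stack([augment_waveform(np.zeros((8, 120)), cfg, rng)
                          for _ in range(120)])
        assert draws.std() == pytest.approx(0.005, rel=0.02)

    def test_too_short_input(self):
        with pytest.raises(InvalidArgumentError):
            augment_waveform(np.zeros((8, 40)), FineTuneConfig(), np.random.default_rng(0))


def _toy_regression_data(n, seed, n_leads=8, length=32, meta_dim=4):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 0.1, size=(n, n_leads, length)).astype(np.float32)
    amp = rng.uniform(0.5, 2.0, size=n).astype(np.float32)
    x[:, 4, 12:20] += amp[:, None]
    meta = rng.normal(size=(n, meta_dim)).astype(np.float32)
    y = 40.0 + 20.0 * (amp - 1.25)
    return x, meta, y


TOY_MODEL = dict(conv_blocks=((8, 5), (12, 3), (8, 3)), fc_hidden=16,
                 metadata_dim=4, beat_length=32,
                 dropout_after_conv=0.1, dropout_between_fc=0.1)


class TestTraining:
    def test_seeded_runs_are_identical(self):
        data = _toy_regression_data(96, 0)
        val = _toy_regression_data(32, 1)
        histories = []
        for _ in range(2):
            model = build_fcn(ModelConfig(**TOY_MODEL, seed=5))
            _, h = train_model(model, data, val,
                              TrainConfig(max_epochs=4, seed=9))
            histories.append((h.train_losses, h.val_losses))
        assert histories[0] == histories[1]

    def test_learning_rate_reduction_value(self):
        # constant targets cannot improve: the rate is cut after the patience
        x = np.zeros((40, 8, 32), dtype=np.float32)
        meta = np.zeros((40, 4), dtype=np.float32)
        y = np.zeros(40)
        model = build_fcn(ModelConfig(**TOY_MODEL, seed=0))
        cfg = TrainConfig(max_epochs=6, lr_reduce_patience=2,
                          early_stop_patience=30, seed=0)
        _, h = train_model(model, (x, meta, y), (x, meta, y), cfg)
        assert 5e-5 in [pytest.approx(lr) for lr in h.learning_rates]

    def test_learns_amplitude_signal(self):
        train = _toy_regression_data(400, 2)
        val = _toy_regression_data(100, 3)
        test = _toy_regression_data(100, 4)
        model = build_fcn(ModelConfig(**TOY_MODEL, seed=1))
        model, h = train_model(model, train, val,
                               TrainConfig(max_epochs=30, seed=2))
        pred = model.predict_raw(test[0], test[1])
        r = np.corrcoef(pred, test[2])[0, 1]
        assert r >= 0.8

    def test_best_weights_restored(self):
        train = _toy_regression_data(96, 5)
        val = _toy_regression_data(48, 6)
        model = build_fcn(ModelConfig(**TOY_MODEL, seed=2))
        model, h = train_model(model, train, val,
                               TrainConfig(max_epochs=8, seed=3))
        from ecglvh.model import _loss_fn
        final_val = _loss_fn("LVM_regression")(
            model.predict_raw(val[0], val[1]), val[2])
        assert final_val == pytest.approx(min(h.val_losses), rel=1e-5)


class TestPredict:
    def test_inference_deterministic_and_order_invariant(self):
        x, meta, _ = _toy_regression_data(30, 7)
        model = build_fcn(ModelConfig(**TOY_MODEL, seed=3))
        a = model.predict_raw(x, meta)
        b = model.predict_raw(x, meta)
        np.testing.assert_array_equal(a, b)
        perm = np.random.default_rng(0).permutation(30)
        np.testing.assert_allclose(model.predict_raw(x[perm], meta[perm]),
                                   a[perm], atol=1e-6)

    def test_classification_outputs_probabilities(self):
        x, meta, _ = _toy_regression_data(10, 8)
        model = build_fcn(ModelConfig(**TOY_MODEL, seed=4,
                                      target="LVH_classification"))
        ps = predict(model, x, meta)
        assert ps.model_variant == "FCN_LVH"
        assert np.all((ps.lvh_probability > 0) & (ps.lvh_probability < 1))


class TestFineTune:
    def test_stage_one_freezes_conv_blocks(self):
        train = _toy_regression_data(64, 9)
        val = _toy_regression_data(32, 10)
        model = build_fcn(ModelConfig(**TOY_MODEL, seed=6))
        before = {name: layer.params[key].copy()
                  for name, layer, key in model.param_refs()
                  if name.startswith("block")}
        cfg = TrainConfig(max_epochs=2, seed=1)
        model, _ = train_model(model, train, val, cfg,
                               trainable={"head"},
                               augment_cfg=FineTuneConfig(crop_max=2))
        for name, layer, key in model.param_refs():
            if name.startswith("block"):
                np.testing.assert_array_equal(layer.params[key], before[name])

    def test_staged_fine_tune_runs_and_reports(self):
        train = _toy_regression_data(64, 11)
        val = _toy_regression_data(32, 12)
        model = build_fcn(ModelConfig(**TOY_MODEL, seed=7))
        model, _ = train_model(model, train, val, TrainConfig(max_epochs=3, seed=2))
        for augment in (True, False):
            m2 = build_fcn(ModelConfig(**TOY_MODEL, seed=7))
            m2.set_weights(model.get_weights())
            ft = FineTuneConfig(crop_max=2, augment=augment, seed=3)
            m2, histories = fine_tune(m2, train, val, ft,
                                      TrainConfig(max_epochs=2, seed=4))
            assert len(histories) == 4  # head + three blocks
            assert all(len(h.val_losses) >= 1 for h in histories)

    def test_fine_tuning_adapts_to_shifted_domain(self):
        # pre-train on one amplitude->target mapping, shift the mapping, and
        # check fine-tuning lowers the error on the shifted domain
        train = _toy_regression_data(256, 13)
        val = _toy_regression_data(96, 14)
        model = build_fcn(ModelConfig(**TOY_MODEL, seed=8))
        model, _ = train_model(model, train, val, TrainConfig(max_epochs=15, seed=5))

        def shift(data):
            x, meta, y = data
            return x, meta, y + 6.0
        ext_train, ext_val = shift(_toy_regression_data(128, 15)), shift(
            _toy_regression_data(64, 16))
        base_mae = np.abs(model.predict_raw(ext_val[0], ext_val[1]) - ext_val[2]).mean()
        tuned, _ = fine_tune(model, ext_train, ext_val,
                             FineTuneConfig(crop_max=2, seed=6),
                             TrainConfig(max_epochs=8, seed=7))
        tuned_mae = np.abs(tuned.predict_raw(ext_val[0], ext_val[1]) - ext_val[2]).mean()
        assert tuned_mae <= base_mae
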