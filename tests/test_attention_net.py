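import numpy as np
import pytest

from chlorospec.attention_net import (
    ChlorophyllCNN,
    ModelConfig,
    _loss_and_grad,
    build_model,
    cosine_annealing_lr,
    forward,
    get_attention_weights,
    se_recalibrate,
    train,
)
from chlorospec.preprocess import AugmentationConfig
from chlorospec.synthetic_data import LeafSpectrumModel, generate_dataset
from chlorospec.hsi_io import trim_to_range

TINY = dict(n_bands=12, se_reduction=3, stem_channels=2, inception_branch_channels=2,
            fc_hidden_size=4)


def zero_parameters(model: ChlorophyllCNN) -> None:
    for _, _, arr in model.parameters():
        arr[:] = 0.0


class TestBuildModel:
    def test_stem_emits_one_sixth_of_input_length(self):
        model = build_model(ModelConfig(n_bands=180))
        assert model.stem_out_len == 30
        x = np.random.default_rng(0).uniform(0, 1, (2, 1, 180))
        h = model.stem_pool.forward(model.stem_relu.forward(model.stem_conv.forward(x)))
        assert h.shape == (2, 16, 30)

    def test_inception_concatenates_four_branches(self):
        model = build_model(ModelConfig(**TINY))
        x = np.random.default_rng(1).uniform(0, 1, (3, 2, 6))
        out = model.inception.forward(x)
        assert out.shape == (3, 4 * 2, 6)

    def test_same_seed_identical_initialization(self):
        a = build_model(ModelConfig(n_bands=180, seed=5))
        b = build_model(ModelConfig(n_bands=180, seed=5))
        for (_, _, pa), (_, _, pb) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)

    def test_parameter_count_matches_hand_computation(self):
        cfg = ModelConfig()  # 180 bands, r=4, 16 stem/branch channels, fc 64
        model = build_model(cfg)
        se = 180 * 45 + 45 + 45 * 180 + 180
        stem = 16 * 1 * 7 + 16
        inception = (16 * 16 * 1 + 16) + (16 * 16 * 3 + 16) + (16 * 16 * 5 + 16) + (16 * 16 * 1 + 16)
        head = (64 * 30) * 64 + 64 + 64 * 1 + 1
        assert model.n_parameters() == se + stem + inception + head

    @pytest.mark.parametrize("bad", [
        dict(n_bands=100),                      # not divisible by 6
        dict(stem_conv_stride=3),               # fixed stride
        dict(inception_kernel_sizes=(1, 3, 7)), # fixed kernel set
        dict(epochs=0),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelConfig(**bad)

    def test_attention_ablation_via_config_switch(self):
        plain = build_model(ModelConfig(use_attention=False, **TINY))
        assert plain.attention is None
        x = np.random.default_rng(2).uniform(0, 1, (1, 12))
        assert np.isfinite(plain.predict(x)).all()


class TestSERecalibrate:
    def test_zero_parameters_give_half_gate(self):
        model = build_model(ModelConfig(**TINY))
        zero_parameters(model)
        x = np.random.default_rng(3).uniform(0, 1, 12)
        out, weights = se_recalibrate(x, model.attention)
        assert np.allclose(weights.values, 0.5)
        assert np.allclose(out, 0.5 * x)

    def test_weights_strictly_in_unit_interval(self):
        model = build_model(ModelConfig(**TINY, seed=7))
        x = np.random.default_rng(4).uniform(0, 1, (5, 12))
        _, weights = se_recalibrate(x, model.attention)
        assert np.all(weights.values > 0) and np.all(weights.values < 1)

    def test_zero_spectrum_maps_to_zero(self):
        model = build_model(ModelConfig(**TINY, seed=8))
        out, _ = se_recalibrate(np.zeros(12), model.attention)
        assert np.allclose(out, 0.0)

    def test_length_mismatch_rejected(self):
        model = build_model(ModelConfig(**TINY))
        with pytest.raises(ValueError):
            se_recalibrate(np.zeros(13), model.attention)


class TestForward:
    def test_all_zero_parameters_output_final_bias(self):
        model = build_model(ModelConfig(**TINY))
        zero_parameters(model)
        model.fc2.params["b"][:] = 3.25
        x = np.random.default_rng(5).uniform(0, 1, 12)
        assert forward(model, x) == pytest.approx(3.25)

    def test_batch_of_one_equals_unbatched(self):
        model = build_model(ModelConfig(**TINY, seed=9))
        x = np.random.default_rng(6).uniform(0, 1, 12)
        assert forward(model, x) == pytest.approx(forward(model, x[None, :])[0])

    def test_inference_is_deterministic(self):
        model = build_model(ModelConfig(**TINY, seed=10))
        x = np.random.default_rng(7).uniform(0, 1, (4, 12))
        assert np.array_equal(model.predict(x), model.predict(x))

    def test_nan_input_rejected(self):
        model = build_model(ModelConfig(**TINY))
        x = np.zeros(12)
        x[3] = np.nan
        with pytest.raises(ValueError):
            forward(model, x)


class TestCosineAnnealing:
    def test_schedule_values(self):
        cfg = ModelConfig(n_bands=180)
        assert cosine_annealing_lr(0, cfg) == pytest.approx(1e-4)
        assert cosine_annealing_lr(100, cfg) == pytest.approx(5e-5)
        assert cosine_annealing_lr(200, cfg) == pytest.approx(1e-4)  # restart

    def test_epoch_out_of_range_rejected(self):
        cfg = ModelConfig(n_bands=180, epochs=10)
        with pytest.raises(ValueError):
            cosine_annealing_lr(10, cfg)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        cfg = ModelConfig(**TINY, seed=1)
        model = build_model(cfg)
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (3, 12))
        y = rng.uniform(10, 40, 3)
        loss, dpred = _loss_and_grad(model, X, y, 0.0)
        model._backward(dpred)
        eps = 1e-6
        for layer, name, arr in model.parameters():
            analytic = layer.grads[name].copy()
            numeric = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = arr[i]
                arr[i] = old + eps
                lp, _ = _loss_and_grad(model, X, y, 0.0)
                arr[i] = old - eps
                lm, _ = _loss_and_grad(model, X, y, 0.0)
                arr[i] = old
                numeric[i] = (lp - lm) / (2 * eps)
            denom = np.abs(analytic) + np.abs(numeric) + 1e-8
            assert np.max(np.abs(analytic - numeric) / denom) < 1e-4


class TestTrain:
    def test_memorizes_six_noise_free_samples(self):
        model_spec = LeafSpectrumModel(noise_sd=0.0)
        ds = generate_dataset(n=6, seed=3, model=model_spec, k_folds=2)
        X, _ = trim_to_range(ds.X, ds.grid, 437, 919)
        cfg = ModelConfig(n_bands=180, epochs=500, seed=4, batch_size=1)
        model = build_model(cfg)
        model, history = train(model, (X, ds.y), cfg=cfg)
        final_mse = np.mean((model.predict(X) - ds.y) ** 2)
        assert final_mse < 0.5

    def test_deterministic_loss_trajectory(self):
        ds = generate_dataset(n=20, seed=5)
        X, _ = trim_to_range(ds.X, ds.grid, 437, 919)
        cfg = ModelConfig(n_bands=180, epochs=3, seed=6, l2_coefficient=0.0)
        runs = []
        for _ in range(2):
            model = build_model(cfg)
            _, history = train(model, (X, ds.y), cfg=cfg)
            runs.append(history.train_loss)
        assert runs[0] == runs[1]

    def test_loss_descends(self):
        ds = generate_dataset(n=40, seed=7)
        X, _ = trim_to_range(ds.X, ds.grid, 437, 919)
        cfg = ModelConfig(n_bands=180, epochs=20, seed=8)
        model = build_model(cfg)
        _, history = train(model, (X, ds.y), cfg=cfg, augment=AugmentationConfig())
        assert history.train_loss[-1] <= history.train_loss[0]
        assert len(history) == 20
        assert all(lr > 0 for lr in history.learning_rate)

    def test_empty_training_set_rejected(self):
        cfg = ModelConfig(**TINY)
        model = build_model(cfg)
        with pytest.raises(ValueError):
            train(model, (np.empty((0, 12)), np.empty(0)), cfg=cfg)


class TestAttentionWeights:
    @pytest.fixture(scope="class")
    def trained(self):
        ds = generate_dataset(n=80, seed=11)
        X, grid = trim_to_range(ds.X, ds.grid, 437, 919)
        from chlorospec.preprocess import minmax_scale_dataset

        Xs = minmax_scale_dataset(X, axis=1)
        cfg = ModelConfig(n_bands=180, epochs=60, seed=12)
        model = build_model(cfg)
        model, _ = train(model, (Xs, ds.y), cfg=cfg, augment=AugmentationConfig())
        return model, Xs, grid

    def test_values_in_unit_interval(self, trained):
        model, Xs, _ = trained
        w = get_attention_weights(model, Xs)
        assert np.all(w.values > 0) and np.all(w.values < 1)

    def test_single_spectrum_average_is_its_own_gate(self, trained):
        model, Xs, _ = trained
        w1 = get_attention_weights(model, Xs[:1])
        _, w2 = se_recalibrate(Xs[0], model.attention)
        assert np.allclose(w1.values, w2.values)

    def test_gate_is_input_dependent_after_training(self, trained):
        # the SE gate recalibrates per spectrum, not with one fixed vector
        model, Xs, _ = trained
        g_low = model.attention.gate(Xs[:1])
        g_high = model.attention.gate(Xs[-1:])
        assert not np.allclose(g_low, g_high)

    def test_gate_develops_band_structure_during_training(self, trained):
        # training differentiates the bands: the mean gate departs from the
        # near-uniform profile of an untrained network
        model, Xs, _ = trained
        fresh = build_model(model.cfg)
        trained_spread = get_attention_weights(model, Xs).values.std()
        fresh_spread = get_attention_weights(fresh, Xs).values.std()
        assert trained_spread > fresh_spread

    def test_empty_input_rejected(self, trained):
        model, _, _ = trained
        with pytest.raises(ValueError):
            get_attention_weights(model, np.empty((0, 180)))
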