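import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emflowtomo import nn
from emflowtomo.networks import (
    LayerSpec,
    NetworkSpec,
    TrainConfig,
    bp_spec,
    build_network,
    cae_specs,
    cnn_spec,
    encode,
    mae,
    normalize_features,
    predict,
    propagate_shapes,
    standardize,
    train_bp,
    train_cae,
    train_cnn,
    save_model,
    load_model,
)


class TestShapePropagation:
    def test_reference_encoder_reproduces_all_output_sizes(self):
        enc, _ = cae_specs()
        assert propagate_shapes(enc) == [
            (11, 2000, 2), (11, 1000, 4), (11, 800, 4),
            (11, 400, 8), (11, 200, 16), (11, 100, 16),
            (11, 50, 32), (11, 25, 60), (11, 11, 60),
        ]

    def test_reference_decoder_reproduces_all_output_sizes(self):
        _, dec = cae_specs()
        assert propagate_shapes(dec) == [
            (11, 25, 60), (11, 50, 60), (11, 100, 32), (11, 200, 32),
            (11, 400, 16), (11, 800, 8), (11, 1000, 8), (11, 2000, 4),
            (11, 2601, 2), (11, 2601, 1),
        ]

    def test_reference_cnn_reproduces_all_output_sizes(self):
        shapes = propagate_shapes(cnn_spec())
        # widths after each block and the dense head
        assert shapes[0] == (11, 30, 6)
        assert shapes[2] == (11, 15, 6)
        assert shapes[5] == (11, 7, 12)
        assert shapes[8] == (11, 6, 24)
        assert shapes[9] == (1, 1, 1584)
        assert shapes[10] == (1, 1, 2601)
        assert shapes[-1] == (1, 1, 2601)

    def test_scaled_specs_preserve_bottleneck_and_output(self):
        enc, dec = cae_specs(11, 441, p=12)
        assert propagate_shapes(enc)[-1] == (11, 11, 12)
        assert propagate_shapes(dec)[-1] == (11, 441, 1)

    def test_non_positive_extent_names_the_layer(self):
        spec = NetworkSpec("bad", (4, 10, 1), [
            LayerSpec("conv", kernel=4, filters=2),
            LayerSpec("maxpool", kernel=9),
        ])
        with pytest.raises(ValueError, match="layer 2"):
            propagate_shapes(spec)


class TestMae:
    def test_identical_arrays(self):
        assert mae(np.ones((3, 4)), np.ones((3, 4))) == 0.0

    def test_hand_computed_example(self):
        assert mae(np.array([0.0, 2.0]), np.array([1.0, 1.0])) == 1.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_elementwise_loop(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=17), rng.normal(size=17)
        acc = sum(abs(x - y) for x, y in zip(a, b)) / 17
        assert mae(a, b) == pytest.approx(acc)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae(np.zeros(3), np.zeros(4))


class TestGradients:
    def test_numeric_vs_analytic_gradient_on_tiny_network(self):
        rng = np.random.default_rng(3)
        spec = NetworkSpec("tiny", (2, 10, 1), [
            LayerSpec("conv", 4, 2, activation="tanh"),
            LayerSpec("batchnorm", activation="sigmoid"),
            LayerSpec("maxpool", 2),
            LayerSpec("bilinear", out_width=8),
            LayerSpec("deconv", 3, 2, stride=2, padding="same", activation="tanh"),
            LayerSpec("flatten"),
            LayerSpec("dense", filters=5),
        ])
        net = build_network(spec, rng)
        x = rng.normal(size=(3, 2, 10, 1))
        target = rng.normal(size=(3, 5))

        pred = net.forward(x, train=True)
        _, g = nn.mae_loss(pred, target)
        net.backward(g)
        analytic = {(i, n): net.layers[i].grads[n].copy() for i, n, _ in net.parameters()}

        eps = 1e-6
        for i, name, p in net.parameters():
            num = np.zeros_like(p)
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = nn.mae_loss(net.forward(x, train=True), target)
                p[idx] = orig - eps
                lm, _ = nn.mae_loss(net.forward(x, train=True), target)
                p[idx] = orig
                num[idx] = (lp - lm) / (2 * eps)
            denom = max(np.abs(analytic[(i, name)]).max(), np.abs(num).max(), 1e-12)
            assert np.abs(analytic[(i, name)] - num).max() / denom < 1e-4


class TestNormalization:
    def test_standardize_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        W = rng.normal(3.0, 2.0, size=(11, 50))
        Ws, stats = standardize(W)
        assert abs(Ws.mean()) < 1e-12
        assert Ws.std() == pytest.approx(1.0)

    def test_reapplying_stored_stats_is_consistent(self):
        rng = np.random.default_rng(1)
        W = rng.normal(size=(4, 9))
        Ws, stats = standardize(W)
        Ws2, _ = standardize(W, stats)
        assert np.array_equal(Ws, Ws2)

    def test_constant_input_maps_to_zero(self):
        W = np.full((3, 5), 2.5)
        Ws, _ = standardize(W)
        assert np.allclose(Ws, 0.0)

    def test_per_feature_normalization(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6, 3)) * np.arange(1, 4)
        Xn, stats = normalize_features(X)
        assert np.allclose(Xn.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Xn.std(axis=0), 1.0)


def _small_W(rng, m=11, n=441):
    return rng.normal(size=(m, n))


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(10)
    W = _small_W(rng)
    cfg = TrainConfig(learning_rate=1e-3, iterations=40, batch_size=1, seed=0)
    return W, train_cae(W, cfg)


@pytest.fixture(scope="module")
def toy_problem():
    rng = np.random.default_rng(20)
    feats = rng.normal(size=(40, 11, 12))
    labels = rng.normal(size=(40, 441)) * 0.1
    return feats, labels


class TestCae:
    def test_loss_history_finite_nonnegative_full_length(self, trained):
        _, model = trained
        h = model.loss_history
        assert len(h) == 40
        assert np.all(np.isfinite(h)) and np.all(h >= 0)

    def test_training_reduces_loss(self, trained):
        _, model = trained
        assert model.loss_history[-1] < model.loss_history[0]

    def test_encode_shape_and_determinism(self, trained):
        W, model = trained
        a = encode(model, W)
        b = encode(model, W)
        assert a.shape == (11, 11, 12)
        assert np.array_equal(a, b)
        assert np.all(np.isfinite(a))

    def test_identity_network_is_a_loss_zero_fixed_point(self):
        # single 1x1 linear conv with unit weight reproduces any input
        layer = nn.Conv(1, 1, 1, rng=np.random.default_rng(0))
        layer.params["w"] = np.ones((1, 1, 1))
        net = nn.Sequential([layer])
        x = np.random.default_rng(1).normal(size=(1, 4, 12, 1))
        loss, _ = nn.mae_loss(net.forward(x), x)
        assert loss == 0.0

    def test_training_is_bit_reproducible(self):
        rng = np.random.default_rng(11)
        W = _small_W(rng)
        cfg = TrainConfig(learning_rate=1e-3, iterations=10, batch_size=1, seed=5)
        a = train_cae(W, cfg)
        b = train_cae(W, cfg)
        assert np.array_equal(a.loss_history, b.loss_history)
        assert np.array_equal(encode(a, W), encode(b, W))


class TestCnn:
    def test_flatten_length_and_output_size(self, toy_problem):
        shapes = propagate_shapes(cnn_spec(11, 12, 441))
        assert shapes[-4] == (1, 1, 396)  # 11 * 3 * 12 after the third block
        assert shapes[-1] == (1, 1, 441)

    def test_inference_is_deterministic_despite_dropout(self, toy_problem):
        feats, labels = toy_problem
        cfg = TrainConfig(learning_rate=1e-3, iterations=15, batch_size=20, seed=1)
        model = train_cnn(feats, labels, cfg)
        a = predict(model, feats[0])
        b = predict(model, feats[0])
        assert np.array_equal(a, b)
        assert a.shape == (441,)

    def test_batch_prediction_matches_per_sample(self, toy_problem):
        feats, labels = toy_problem
        cfg = TrainConfig(learning_rate=1e-3, iterations=10, batch_size=20, seed=2)
        model = train_cnn(feats, labels, cfg)
        batch = predict(model, feats[:4])
        singles = np.stack([predict(model, feats[i]) for i in range(4)])
        assert np.allclose(batch, singles, atol=1e-12)

    def test_sample_count_mismatch_rejected(self, toy_problem):
        feats, labels = toy_problem
        with pytest.raises(ValueError, match="count"):
            train_cnn(feats, labels[:-3], TrainConfig(learning_rate=1e-3, iterations=1, batch_size=8))

    def test_checkpoint_roundtrip_reproduces_predictions(self, tmp_path, toy_problem):
        feats, labels = toy_problem
        cfg = TrainConfig(learning_rate=1e-3, iterations=10, batch_size=20, seed=3)
        model = train_cnn(feats, labels, cfg)
        save_model(model, tmp_path / "cnn.npz")
        back = load_model(tmp_path / "cnn.npz")
        assert np.array_equal(predict(model, feats[:3]), predict(back, feats[:3]))


class TestBp:
    def test_output_length_and_seed_determinism(self):
        rng = np.random.default_rng(30)
        U = rng.normal(size=(30, 11))
        labels = rng.normal(size=(30, 441)) * 0.1
        cfg = TrainConfig(learning_rate=1e-3, iterations=20, batch_size=30, seed=4)
        a = train_bp(U, labels, cfg)
        b = train_bp(U, labels, cfg)
        pa = predict(a, U[0])
        assert pa.shape == (441,)
        assert np.array_equal(pa, predict(b, U[0]))
        assert a.loss_history[-1] < a.loss_history[0]

    def test_spec_has_single_hidden_layer_by_default(self):
        spec = bp_spec(11, 441)
        kinds = [l.kind for l in spec.layers]
        assert kinds == ["flatten", "dense", "dense"]


class TestTrainingStability:
    def test_cae_loss_trailing_average_decreases(self):
        rng = np.random.default_rng(40)
        W = _small_W(rng)
        cfg = TrainConfig(learning_rate=1e-3, iterations=120, batch_size=1, seed=6)
        model = train_cae(W, cfg)
        h = model.loss_history
        first = h[:20].mean()
        last = h[-20:].mean()
        assert last < first
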