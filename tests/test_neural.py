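"""Neural regressors: primitives vs brute-force oracles, gradients, training."""

import numpy as np
import pytest

from nirdry.neural import (
    AdamState,
    TrainConfig,
    TrainingDiverged,
    adam_step,
    architecture_sweep,
    backprop_gradients,
    build_ann,
    build_cnn,
    build_dnn,
    conv1d_forward,
    dense_forward,
    forward,
    he_init_sigma,
    predict,
    relu,
    sgd_step,
    train,
)


class TestActivationAndInit:
    @pytest.mark.parametrize("x, a, expected", [(-3.0, 1.0, 0.0), (2.0, 1.0, 2.0), (2.0, 0.5, 1.0)])
    def test_relu(self, x, a, expected):
        assert relu(x, a) == expected

    def test_relu_slope_must_be_positive(self):
        with pytest.raises(ValueError):
            relu(1.0, 0.0)

    @pytest.mark.parametrize("n, expected", [(2, 1.0), (8, 0.5), (256, np.sqrt(2 / 256))])
    def test_he_sigma(self, n, expected):
        assert he_init_sigma(n) == pytest.approx(expected)

    def test_he_init_empirical_sd(self):
        """Sampled initial weights match sqrt(2/N) within 2%."""
        net = build_ann(400, input_dim=256, seed=0)
        W = net.layers[0].W  # 102400 samples, fan-in 256
        assert W.std() == pytest.approx(he_init_sigma(256), rel=0.02)
        assert abs(W.mean()) < 0.01


class TestForwardOracles:
    def test_dense_identity_and_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert np.allclose(dense_forward(x, np.eye(3), np.zeros(3)), x)
        assert np.allclose(dense_forward(x, np.zeros((3, 4))), np.zeros(4))

    def test_dense_matches_double_loop(self, rng):
        x = rng.normal(size=(4, 6))
        W = rng.normal(size=(6, 3))
        b = rng.normal(size=3)
        oracle = np.empty((4, 3))
        for i in range(4):
            for j in range(3):
                acc = b[j]
                for k in range(6):
                    acc += x[i, k] * W[k, j]
                oracle[i, j] = acc
        assert np.allclose(dense_forward(x, W, b), oracle, atol=1e-12)

    def test_conv_delta_kernel_is_identity(self):
        x = np.abs(np.arange(10.0))
        delta = np.zeros((1, 5))
        delta[0, 2] = 1.0
        out = conv1d_forward(x, delta)
        assert np.allclose(out[0], x[2:-2])

    def test_conv_ones_kernel_on_constant(self):
        out = conv1d_forward(np.full(9, 3.0), np.ones((1, 5)))
        assert np.allclose(out, 15.0)

    def test_conv_matches_sliding_window_loop(self, rng):
        x = rng.normal(size=(3, 12))
        K = rng.normal(size=(2, 5))
        b = rng.normal(size=2)
        out = conv1d_forward(x, K, b)
        for bi in range(3):
            for f in range(2):
                for w in range(12 - 5 + 1):
                    acc = b[f]
                    for k in range(5):
                        acc += x[bi, w + k] * K[f, k]
                    assert out[bi, f, w] == pytest.approx(acc, abs=1e-12)

    def test_kernel_longer_than_input_rejected(self):
        with pytest.raises(ValueError):
            conv1d_forward(np.arange(3.0), np.ones((1, 5)))


class TestOptimizers:
    def test_sgd_examples(self):
        assert sgd_step(1.0, 2.0, 0.1) == pytest.approx(0.8)
        assert sgd_step(np.array([1.0]), np.array([0.0]), 0.5)[0] == 1.0
        w = np.array([2.0])
        g = np.array([1.0])
        two_half = sgd_step(sgd_step(w, g, 0.05), g, 0.05)
        assert np.allclose(two_half, sgd_step(w, g, 0.1))

    def test_adam_first_step_magnitude(self):
        cfg = TrainConfig(learning_rate=0.01)
        params = [(np.array([[1.0]]), np.array([0.0]))]
        grads = [(np.array([[1.0]]), np.array([0.0]))]
        new_params, _ = adam_step(params, grads, AdamState.init(params), cfg)
        # bias-corrected first step: delta = -eta * g / (|g| + eps) ~ -eta
        assert new_params[0][0][0, 0] == pytest.approx(1.0 - 0.01, abs=1e-6)

    def test_adam_zero_gradient_no_motion(self):
        cfg = TrainConfig()
        params = [(np.ones((2, 2)), np.zeros(2))]
        grads = [(np.zeros((2, 2)), np.zeros(2))]
        state = AdamState.init(params)
        for _ in range(5):
            params, state = adam_step(params, grads, state, cfg)
        assert np.allclose(params[0][0], 1.0)

    def test_adam_minimizes_quadratic(self):
        cfg = TrainConfig(learning_rate=0.01)
        params = [(np.array([[5.0]]), np.zeros(1))]
        state = AdamState.init(params)
        for _ in range(2000):
            w = params[0][0]
            grads = [(2.0 * w, np.zeros(1))]  # d/dw of w^2
            params, state = adam_step(params, grads, state, cfg)
        assert abs(params[0][0][0, 0]) < 1e-3


def _finite_difference_check(net, X, y, h=1e-5, rtol=1e-4):
    # move biases off zero so no ReLU pre-activation sits exactly on the
    # kink, where central differences straddle the non-differentiable point
    bias_rng = np.random.default_rng(99)
    for ly in net.layers:
        if ly.b is not None:
            ly.b += bias_rng.uniform(0.05, 0.15, size=ly.b.shape)
    grads = backprop_gradients(net, X, y)

    def loss():
        return float(np.mean((forward(net, X) - y) ** 2))

    params = net.parameters()
    for (W, b), (gW, gb) in zip(params, grads):
        for arr, g in ((W, gW), (b, gb)):
            flat = arr.ravel()
            idxs = np.linspace(0, flat.size - 1, min(flat.size, 8)).astype(int)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + h
                up = loss()
                flat[i] = orig - h
                down = loss()
                flat[i] = orig
                fd = (up - down) / (2 * h)
                scale = max(abs(fd), abs(g.ravel()[i]), 1e-8)
                assert abs(fd - g.ravel()[i]) / scale < rtol


class TestBackprop:
    @pytest.mark.parametrize(
        "builder",
        [
            lambda: build_ann(4, input_dim=6, seed=1),
            lambda: build_dnn(3, input_dim=6, seed=2),
            lambda: build_cnn(2, dense_nodes=4, kernel_size=3, input_dim=10, seed=3),
        ],
        ids=["ann", "dnn", "cnn"],
    )
    def test_matches_finite_differences(self, builder, rng):
        net = builder()
        X = rng.normal(size=(5, net.input_dim))
        y = rng.normal(size=5)
        _finite_difference_check(net, X, y)

    def test_zero_error_zero_output_gradient(self, rng):
        net = build_ann(4, input_dim=6, seed=0)
        X = rng.normal(size=(3, 6))
        y = forward(net, X)  # exact targets -> zero residual
        grads = backprop_gradients(net, X, y)
        gW_out, gb_out = grads[-1]
        assert np.allclose(gW_out, 0.0) and np.allclose(gb_out, 0.0)

    def test_batch_gradient_is_mean_of_per_sample(self, rng):
        net = build_ann(3, input_dim=4, seed=4)
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        batch = backprop_gradients(net, X, y)
        summed = [
            (np.zeros_like(W), np.zeros_like(b)) for W, b in net.parameters()
        ]
        for i in range(6):
            gi = backprop_gradients(net, X[i : i + 1], y[i : i + 1])
            summed = [(sW + gW, sb + gb) for (sW, sb), (gW, gb) in zip(summed, gi)]
        for (bW, bb), (sW, sb) in zip(batch, summed):
            assert np.allclose(bW, sW / 6, atol=1e-12)
            assert np.allclose(bb, sb / 6, atol=1e-12)


class TestBuilders:
    def test_ann_parameter_count(self):
        assert build_ann(200).n_parameters() == 256 * 200 + 200 + 200 * 1 + 1  # 51601

    def test_cnn_conv_stage_is_small(self):
        cnn = build_cnn(6, dense_nodes=200)
        conv = cnn.layers[0]
        assert conv.W.size + conv.b.size == 6 * 5 + 6  # 36 parameters
        assert cnn.layers[0].W.shape == (6, 5)

    def test_networks_have_256_inputs_and_one_output(self):
        for net in (build_ann(50), build_dnn(50), build_cnn(4)):
            assert net.input_dim == 256
            out_layer = net.layers[-1]
            assert out_layer.W.shape[1] == 1
            assert not out_layer.activate

    def test_shape_consistency(self, rng):
        for net in (build_ann(17), build_dnn(9), build_cnn(3, dense_nodes=11)):
            pred = forward(net, rng.normal(size=(4, 256)))
            assert pred.shape == (4,)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            build_ann(0)
        with pytest.raises(ValueError):
            build_cnn(2, kernel_size=4)


class TestTraining:
    def test_zero_learning_rate_is_noop(self, rng):
        net = build_ann(4, input_dim=8, seed=0)
        X = rng.normal(size=(10, 8))
        y = rng.normal(size=10)
        fitted, history = train(net, X, y, TrainConfig(epochs=5, learning_rate=0.0, optimizer="sgd"))
        for (W0, b0), (W1, b1) in zip(net.parameters(), fitted.parameters()):
            assert np.array_equal(W0, W1) and np.array_equal(b0, b1)
        assert np.ptp(history) == 0.0

    def test_memorizes_single_sample(self, rng):
        net = build_ann(4, input_dim=8, seed=1)
        X = rng.uniform(size=(1, 8))
        y = np.array([0.7])
        _, history = train(net, X, y, TrainConfig(epochs=500, seed=0))
        assert history[-1] < 1e-4

    def test_deterministic_history(self, rng):
        net = build_ann(6, input_dim=8, seed=2)
        X = rng.uniform(size=(20, 8))
        y = rng.uniform(size=20)
        cfg = TrainConfig(epochs=10, seed=3)
        _, h1 = train(net, X, y, cfg)
        _, h2 = train(net, X, y, cfg)
        assert np.array_equal(h1, h2)

    def test_loss_decreases_on_well_conditioned_problem(self, rng):
        net = build_ann(8, input_dim=8, seed=0)
        X = rng.uniform(size=(40, 8))
        y = X @ rng.uniform(size=8) / 8
        _, history = train(net, X, y, TrainConfig(epochs=50, seed=0))
        assert history[-1] <= history[0]

    def test_divergence_detected(self, rng):
        net = build_ann(8, input_dim=8, seed=0)
        X = rng.uniform(size=(10, 8))
        y = rng.uniform(size=10)
        with pytest.raises(TrainingDiverged):
            train(net, X, y, TrainConfig(epochs=50, optimizer="sgd", learning_rate=1e6))


class TestArchitectureSweep:
    def test_single_configuration_single_row(self, rng):
        from nirdry.chemometrics import SplitSpec

        X = rng.uniform(size=(24, 16))
        y = rng.uniform(size=24)
        table = architecture_sweep(
            build_ann, [4], X, y, SplitSpec(seed=0), TrainConfig(epochs=5, seed=0)
        )
        assert len(table) == 1
        assert set(table.columns) >= {"parameter", "rmsec", "rmsev", "r2_val"}

    def test_empty_grid_rejected(self, rng):
        from nirdry.chemometrics import SplitSpec

        with pytest.raises(ValueError):
            architecture_sweep(build_ann, [], np.zeros((8, 4)), np.arange(8.0), SplitSpec())
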