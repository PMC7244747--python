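"""Autodiff engine gradients and FD-UNet training/inference contracts."""

import numpy as np
import pytest

from paxel.nn.autograd import (
    Tensor,
    batchnorm,
    concat,
    conv2d,
    conv_transpose2x2,
    maxpool2x2,
    mse_loss,
    relu,
)
from paxel.nn.fdunet import (
    FDUNetSpec,
    TrainConfig,
    build_fdunet,
    predict_mdirect,
    predict_pixeldl,
    predict_postdl,
    train,
)


def directional_check(build_loss, params, rng, eps=1e-2, tol=5e-2):
    """Analytic directional derivative vs central finite difference."""
    loss = build_loss()
    loss.backward()
    dirs = [rng.standard_normal(p.data.shape).astype(np.float32) for p in params]
    analytic = sum(float(np.vdot(p.grad, d)) for p, d in zip(params, dirs))
    for p, d in zip(params, dirs):
        p.data += eps * d
    lp = float(build_loss().data)
    for p, d in zip(params, dirs):
        p.data -= 2 * eps * d
    lm = float(build_loss().data)
    for p, d in zip(params, dirs):
        p.data += eps * d
    numeric = (lp - lm) / (2 * eps)
    assert numeric == pytest.approx(analytic, rel=tol)


class TestAutogradOps:
    def test_conv2d_gradients(self):
        rng = np.random.default_rng(0)
        xd = rng.standard_normal((2, 3, 6, 6)).astype(np.float32)
        wd = (0.3 * rng.standard_normal((4, 3, 3, 3))).astype(np.float32)
        tgt = rng.standard_normal((2, 4, 6, 6)).astype(np.float32)
        x = Tensor(xd, requires_grad=True)
        w = Tensor(wd, requires_grad=True)
        directional_check(lambda: mse_loss(conv2d(x, w), tgt), [x, w], rng)

    def test_conv_transpose_doubles_and_inverts_shapes(self):
        rng = np.random.default_rng(1)
        x = Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32), requires_grad=True)
        w = Tensor(rng.standard_normal((4, 2, 2, 2)).astype(np.float32), requires_grad=True)
        out = conv_transpose2x2(x, w)
        assert out.shape == (1, 2, 16, 16)
        tgt = rng.standard_normal(out.shape).astype(np.float32)
        directional_check(lambda: mse_loss(conv_transpose2x2(x, w), tgt), [x, w], rng)

    def test_maxpool_routes_gradient_to_argmax(self):
        x = Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]], dtype=np.float32),
                   requires_grad=True)
        out = maxpool2x2(x)
        assert out.data.item() == 4.0
        out.backward(np.ones((1, 1, 1, 1), dtype=np.float32))
        np.testing.assert_array_equal(x.grad[0, 0], [[0, 0], [0, 1]])

    def test_batchnorm_normalizes_and_backprops(self):
        rng = np.random.default_rng(2)
        xd = (3.0 + 2.0 * rng.standard_normal((4, 3, 5, 5))).astype(np.float32)
        x = Tensor(xd, requires_grad=True)
        gamma = Tensor(np.ones(3, dtype=np.float32), requires_grad=True)
        beta = Tensor(np.zeros(3, dtype=np.float32), requires_grad=True)
        running = {"mean": np.zeros(3, np.float32), "var": np.ones(3, np.float32)}
        out = batchnorm(x, gamma, beta, running, training=True)
        assert np.abs(out.data.mean(axis=(0, 2, 3))).max() < 1e-5
        assert np.abs(out.data.var(axis=(0, 2, 3)) - 1).max() < 1e-3
        tgt = rng.standard_normal(xd.shape).astype(np.float32)
        directional_check(
            lambda: mse_loss(batchnorm(x, gamma, beta, running, training=True), tgt),
            [x, gamma, beta], rng)

    def test_concat_splits_gradient(self):
        a = Tensor(np.ones((1, 2, 2, 2), dtype=np.float32), requires_grad=True)
        b = Tensor(np.ones((1, 3, 2, 2), dtype=np.float32), requires_grad=True)
        out = concat([a, b])
        g = np.arange(out.data.size, dtype=np.float32).reshape(out.shape)
        out.backward(g)
        np.testing.assert_array_equal(a.grad, g[:, :2])
        np.testing.assert_array_equal(b.grad, g[:, 2:])

    def test_relu_masks_gradient(self):
        x = Tensor(np.array([-1.0, 2.0], dtype=np.float32).reshape(1, 1, 1, 2),
                   requires_grad=True)
        out = relu(x)
        out.backward(np.ones_like(out.data))
        np.testing.assert_array_equal(x.grad.ravel(), [0.0, 1.0])


class TestFDUNet:
    def test_output_shape_matches_input(self):
        model = build_fdunet(FDUNetSpec.desk(in_channels=5), seed=0)
        x = np.random.default_rng(0).standard_normal((1, 5, 32, 32)).astype(np.float32)
        out = model.net(Tensor(x))
        assert out.shape == (1, 1, 32, 32)

    def test_seeded_initialization_reproducible(self):
        a = build_fdunet(FDUNetSpec.desk(2), seed=9)
        b = build_fdunet(FDUNetSpec.desk(2), seed=9)
        c = build_fdunet(FDUNetSpec.desk(2), seed=10)
        for pa, pb in zip(a.net.parameters(), b.net.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)
        assert any(not np.array_equal(pa.data, pc.data)
                   for pa, pc in zip(a.net.parameters(), c.net.parameters()))

    def test_parameter_count_grows_with_growth_rate(self):
        small = build_fdunet(FDUNetSpec(in_channels=1, growth_rate_init=16,
                                        features_init=32, levels=2,
                                        dense_layers_per_block=2), approach="postdl")
        big = build_fdunet(FDUNetSpec(in_channels=1, growth_rate_init=32,
                                      features_init=32, levels=2,
                                      dense_layers_per_block=2), approach="postdl")
        assert big.n_parameters() > small.n_parameters()

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            build_fdunet(FDUNetSpec.desk(in_channels=4), approach="postdl")

    def test_odd_spatial_dims_rejected(self):
        model = build_fdunet(FDUNetSpec.desk(1), approach="mdirectdl")
        with pytest.raises(ValueError):
            train(model, np.zeros((1, 1, 30, 30), np.float32),
                  np.zeros((1, 30, 30), np.float32), TrainConfig.desk(epochs=1))


class TestTraining:
    def test_overfits_single_pair(self):
        """Capacity sanity: one (input, target) pair is drivable to tiny MSE."""
        rng = np.random.default_rng(0)
        model = build_fdunet(FDUNetSpec.desk(1), seed=0, approach="mdirectdl")
        x = rng.random((1, 1, 32, 32)).astype(np.float32)
        y = rng.random((1, 32, 32)).astype(np.float32)
        train(model, x, y, TrainConfig(learning_rate=1e-3, batch_size=1,
                                       epochs=200, seed=0))
        assert model.loss_history[-1] < 1e-3

    def test_training_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(1)
        x = rng.random((6, 1, 16, 16)).astype(np.float32)
        y = rng.random((6, 16, 16)).astype(np.float32)
        losses = []
        for _ in range(2):
            model = build_fdunet(FDUNetSpec(in_channels=1, growth_rate_init=2,
                                            features_init=4, levels=1,
                                            dense_layers_per_block=1),
                                 seed=3, approach="mdirectdl")
            train(model, x, y, TrainConfig(learning_rate=1e-3, batch_size=2,
                                           epochs=3, seed=5))
            losses.append(model.loss_history)
        assert losses[0] == losses[1]


class TestPredict:
    def test_postdl_zero_network_is_identity(self):
        model = build_fdunet(FDUNetSpec.desk(1, residual=True), seed=0, approach="postdl")
        for p in model.net.parameters():
            p.data[:] = 0.0
        x = np.random.default_rng(0).random((32, 32))
        out = predict_postdl(model, x)
        np.testing.assert_allclose(out, x / x.max(), atol=1e-6)

    def test_predict_shapes_and_finiteness(self):
        rng = np.random.default_rng(2)
        m_pix = build_fdunet(FDUNetSpec.desk(4), seed=0, approach="pixeldl")
        out = predict_pixeldl(m_pix, rng.standard_normal((32, 32, 4)))
        assert out.shape == (32, 32) and np.isfinite(out).all() and out.min() >= 0
        m_md = build_fdunet(FDUNetSpec.desk(1), seed=0, approach="mdirectdl")
        out = predict_mdirect(m_md, rng.standard_normal((32, 32)))
        assert out.shape == (32, 32) and np.isfinite(out).all()

    def test_channel_order_matters_for_pixeldl(self):
        """Sensor channels are not interchangeable: permuting them changes the
        output, documenting the channel-order contract."""
        rng = np.random.default_rng(3)
        model = build_fdunet(FDUNetSpec.desk(4), seed=1, approach="pixeldl")
        vol = rng.standard_normal((32, 32, 4)).astype(np.float32)
        out1 = predict_pixeldl(model, vol)
        out2 = predict_pixeldl(model, vol[:, :, ::-1].copy())
        assert not np.allclose(out1, out2)

    def test_wrong_approach_rejected(self):
        model = build_fdunet(FDUNetSpec.desk(1), seed=0, approach="mdirectdl")
        with pytest.raises(ValueError):
            predict_postdl(model, np.zeros((32, 32)))
        with pytest.raises(ValueError):
            predict_pixeldl(model, np.zeros((32, 32, 4)))
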