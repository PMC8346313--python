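import numpy as np
import pytest

from echoenhance import enhancer as enh
from echoenhance.enhancer import (
    Activation,
    ConvLayer,
    EnhancerNet,
    TrainConfig,
    conv2d,
    default_net,
    forward,
    identity_net,
    load_net,
    loss_and_grads,
    mse_loss,
    relu,
    relu_grad,
    save_net,
    sgd_step,
    swish,
    train,
)
from echoenhance.image import EchoImage
from echoenhance.phantom import DegradationSpec, default_phantom_spec, make_paired_dataset


def conv_oracle(x, weights, bias):
    """Direct nested-loop correlation with reflect padding (independent oracle)."""
    out_ch, in_ch, f, _ = weights.shape
    pad = f // 2
    _, h, w = x.shape
    padded = np.stack([np.pad(c, pad, mode="reflect") for c in x])
    out = np.zeros((out_ch, h, w))
    for o in range(out_ch):
        for i in range(in_ch):
            for r in range(h):
                for c in range(w):
                    for kr in range(f):
                        for kc in range(f):
                            out[o, r, c] += padded[i, r + kr, c + kc] * weights[o, i, kr, kc]
        out[o] += bias[o]
    return out


class TestConv2d:
    def test_identity_kernel(self, rng):
        x = rng.random((1, 6, 7))
        layer = ConvLayer(np.ones((1, 1, 1, 1)), np.zeros(1))
        np.testing.assert_allclose(conv2d(x, layer), x)

    def test_all_ones_kernel_on_constant(self):
        c, b = 0.3, 0.1
        x = np.full((1, 8, 8), c)
        layer = ConvLayer(np.ones((1, 1, 3, 3)), np.array([b]))
        out = conv2d(x, layer)
        # constant field: reflect padding keeps every pixel (not just interior) at 9c + b
        np.testing.assert_allclose(out, 9 * c + b)

    def test_matches_bruteforce_oracle(self, rng):
        x = rng.standard_normal((1, 5, 5))
        weights = rng.standard_normal((1, 1, 3, 3))
        bias = rng.standard_normal(1)
        layer = ConvLayer(weights, bias)
        np.testing.assert_allclose(conv2d(x, layer), conv_oracle(x, weights, bias), atol=1e-10)

    @pytest.mark.parametrize("trial", range(10))
    def test_multichannel_oracle(self, rng, trial):
        in_ch, out_ch = int(rng.integers(1, 4)), int(rng.integers(1, 4))
        f = int(rng.choice([1, 3, 5]))
        x = rng.standard_normal((in_ch, 6, 8))
        weights = rng.standard_normal((out_ch, in_ch, f, f))
        bias = rng.standard_normal(out_ch)
        layer = ConvLayer(weights, bias)
        np.testing.assert_allclose(conv2d(x, layer), conv_oracle(x, weights, bias), atol=1e-10)

    def test_channel_mismatch_rejected(self, rng):
        layer = ConvLayer(rng.standard_normal((2, 3, 3, 3)), np.zeros(2))
        with pytest.raises(ValueError, match="channels"):
            conv2d(rng.random((2, 5, 5)), layer)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            ConvLayer(rng.standard_normal((1, 1, 4, 4)), np.zeros(1))


class TestActivations:
    def test_relu_negative(self):
        assert relu(-3.0) == 0.0

    def test_relu_positive(self):
        assert relu(2.0) == 2.0

    def test_relu_grad_boundary_convention(self):
        assert relu_grad(0.0) == 0.0
        assert relu_grad(1.0) == 1.0
        assert relu_grad(-1.0) == 0.0

    def test_swish_zero_gate(self):
        assert swish(0.0, alpha=3.7) == 0.0

    def test_swish_saturates_to_identity(self):
        # exact gap is 20 * e^-20 / (1 + e^-20) ~ 4.1e-8
        assert abs(swish(20.0, 1.0) - 20.0) < 1e-7
        assert abs(swish(40.0, 1.0) - 40.0) < 1e-8

    def test_swish_at_one(self):
        # independent arithmetic: 1 / (1 + e^-1)
        assert swish(1.0, 1.0) == pytest.approx(1.0 / (1.0 + np.exp(-1.0)), abs=1e-12)
        assert swish(1.0, 1.0) == pytest.approx(0.731059, abs=1e-6)


class TestForward:
    def test_identity_network_is_identity(self, rng):
        img = EchoImage(rng.random((9, 11)))
        out = forward(identity_net(), img)
        np.testing.assert_allclose(out.pixels, img.pixels)

    def test_same_size_output(self, rng):
        img = EchoImage(rng.random((17, 23)))
        out = forward(default_net(seed=0, feature_channels=4, mapping_channels=3), img)
        assert out.shape == img.shape

    def test_composition_oracle(self, rng):
        # stage-by-stage composition with the brute-force conv oracle
        net = default_net(seed=3, feature_channels=2, mapping_channels=2)
        img = EchoImage(rng.random((8, 8)))
        x = img.pixels[None]
        for idx, layer in enumerate(net.layers):
            x = conv_oracle(x, layer.weights, layer.bias)
            if idx < len(net.layers) - 1:
                x = swish(x, layer.alpha)
        expected = np.clip(x[0], 0.0, 1.0)
        np.testing.assert_allclose(forward(net, img).pixels, expected, atol=1e-10)

    def test_output_clipped(self, rng):
        layers = [
            ConvLayer(np.ones((1, 1, 1, 1)) * 5.0, np.zeros(1), Activation.NONE)
            for _ in range(3)
        ]
        out = forward(EnhancerNet(layers), EchoImage(rng.random((5, 5))))
        assert out.pixels.max() <= 1.0


class TestMseLoss:
    def test_identical_images(self, rng):
        img = EchoImage(rng.random((6, 6)))
        assert mse_loss(img, img) == 0.0

    def test_constant_difference(self):
        a = EchoImage(np.full((4, 4), 0.7))
        b = EchoImage(np.full((4, 4), 0.4))
        assert mse_loss(a, b) == pytest.approx(0.09, abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        p = rng.random((7, 5))
        t = rng.random((7, 5))
        total = 0.0
        for i in range(7):
            for j in range(5):
                total += (p[i, j] - t[i, j]) ** 2
        assert mse_loss(p, t) == pytest.approx(total / 35, abs=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            mse_loss(rng.random((4, 4)), rng.random((5, 4)))


class TestSgdStep:
    def test_zero_gradients_leave_params(self, rng):
        params = [rng.random((2, 2)), 0.5]
        out = sgd_step(params, [np.zeros((2, 2)), 0.0], beta=0.1)
        np.testing.assert_array_equal(out[0], params[0])
        assert out[1] == 0.5

    def test_quadratic_converges(self):
        # f(R) = R^2, closed form R_t = (1 - 2*beta)^t * R_0 = 0.8^t
        r = 1.0
        for _ in range(100):
            (r,) = sgd_step([r], [2 * r], beta=0.1)
        assert abs(r) < 1e-9
        assert r == pytest.approx(0.8**100, rel=1e-9)

    def test_step_linear_in_beta(self, rng):
        p = rng.random((3, 3))
        g = rng.standard_normal((3, 3))
        d1 = p - sgd_step([p], [g], beta=0.05)[0]
        d2 = p - sgd_step([p], [g], beta=0.10)[0]
        np.testing.assert_allclose(d2, 2 * d1)

    def test_beta_zero_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            sgd_step([1.0], [1.0], beta=0.0)


def _tiny_pairs(n=4, size=24, seed=0):
    spec = default_phantom_spec(size, size)
    deg = DegradationSpec(speckle_sigma=0.2, blur_sigma=1.0, seed=seed)
    return make_paired_dataset(n, spec, deg, jitter_seed=seed)


class TestTrain:
    def test_empty_dataset_rejected(self):
        net = default_net(seed=0, feature_channels=2, mapping_channels=2)
        with pytest.raises(ValueError, match="at least one"):
            train(net, [], TrainConfig(epochs=1))

    def test_vanishing_learning_rate_is_noop(self):
        pairs = _tiny_pairs()
        net = default_net(seed=0, feature_channels=2, mapping_channels=2)
        initial = np.mean([mse_loss(forward(net, noisy), clean) for clean, noisy in pairs])
        _, trace = train(net, pairs, TrainConfig(learning_rate=1e-12, epochs=1, seed=0))
        assert trace[0] == pytest.approx(initial, abs=1e-6)

    def test_deterministic_given_seed(self):
        pairs = _tiny_pairs()
        cfg = TrainConfig(learning_rate=0.05, batch_size=2, epochs=3, seed=11)
        _, trace_a = train(default_net(seed=5, feature_channels=2, mapping_channels=2), pairs, cfg)
        _, trace_b = train(default_net(seed=5, feature_channels=2, mapping_channels=2), pairs, cfg)
        assert trace_a == trace_b

    def test_loss_trace_mostly_nonincreasing(self):
        pairs = _tiny_pairs(n=6)
        net = default_net(seed=2, feature_channels=4, mapping_channels=3)
        _, trace = train(net, pairs, TrainConfig(learning_rate=0.05, batch_size=2, epochs=30, seed=2))
        drops = sum(b <= a for a, b in zip(trace, trace[1:]))
        assert drops >= 0.9 * (len(trace) - 1)

    def test_training_reduces_loss(self):
        pairs = _tiny_pairs(n=6)
        net = default_net(seed=2, feature_channels=4, mapping_channels=3)
        _, trace = train(net, pairs, TrainConfig(learning_rate=0.1, batch_size=2, epochs=25, seed=2))
        assert trace[-1] < trace[0]


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        # 2-layer toy net plus reconstruction; central differences at 1e-4 relative
        net = EnhancerNet(
            [
                ConvLayer(0.3 * rng.standard_normal((2, 1, 3, 3)), rng.standard_normal(2), Activation.SWISH),
                ConvLayer(0.3 * rng.standard_normal((2, 2, 3, 3)), rng.standard_normal(2), Activation.RELU),
                ConvLayer(0.3 * rng.standard_normal((1, 2, 3, 3)), rng.standard_normal(1), Activation.NONE),
            ]
        )
        noisy = rng.random((7, 7))
        clean = rng.random((7, 7))
        _, grads = loss_and_grads(net, noisy, clean, clip=False)
        params = net.parameters()
        eps = 1e-6
        for pi in range(len(params)):
            if np.ndim(params[pi]) == 0:
                coords = [None]
            else:
                flat_count = params[pi].size
                picks = rng.choice(flat_count, size=min(6, flat_count), replace=False)
                coords = [np.unravel_index(k, params[pi].shape) for k in picks]
            for idx in coords:
                def perturbed(delta):
                    plist = [np.array(p, dtype=float) if np.ndim(p) else p for p in params]
                    if idx is None:
                        plist[pi] = plist[pi] + delta
                    else:
                        plist[pi][idx] += delta
                    net.set_parameters(plist)
                    loss, _ = loss_and_grads(net, noisy, clean, clip=False)
                    return loss

                fd = (perturbed(eps) - perturbed(-eps)) / (2 * eps)
                net.set_parameters(params)
                g = grads[pi] if idx is None else grads[pi][idx]
                assert abs(fd - g) <= 1e-4 * max(1.0, abs(fd), abs(g))


class TestNetPlumbing:
    def test_fewer_than_three_layers_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 3"):
            EnhancerNet([ConvLayer(np.ones((1, 1, 1, 1)), np.zeros(1))] * 2)

    def test_channel_chain_validated(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            EnhancerNet(
                [
                    ConvLayer(rng.standard_normal((4, 1, 3, 3)), np.zeros(4)),
                    ConvLayer(rng.standard_normal((2, 3, 3, 3)), np.zeros(2)),
                    ConvLayer(rng.standard_normal((1, 2, 3, 3)), np.zeros(1)),
                ]
            )

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        net = default_net(seed=9, feature_channels=2, mapping_channels=2)
        path = tmp_path / "model.json"
        save_net(net, path, metadata={"note": "test"})
        loaded = load_net(path)
        img = EchoImage(rng.random((10, 10)))
        np.testing.assert_allclose(forward(loaded, img).pixels, forward(net, img).pixels)

    def test_load_rejects_foreign_json(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"hello": 1}')
        with pytest.raises(ValueError, match="checkpoint"):
            load_net(path)
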