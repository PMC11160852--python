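"""Convolutional kernels: forward/backward/update against loop and
finite-difference oracles, and the dense reductions."""

import numpy as np
import pytest

from pfanet.conv_net import (ConvLayer, conv_forward_raw, conv_input_grad,
                             conv_weight_grad, error_bp_conv, error_fa_conv,
                             error_pfa_conv, update_conv_R, update_conv_W)
from pfanet.core_net import DenseLayer, Network, output_error
from pfanet.error_rules import FeedbackState, backward
from pfanet.exceptions import DimensionError
from pfanet.harness import build_conv_network, run_experiment, seed_stream
from pfanet.metrics import compose_path_conv
from pfanet.randmat import init_semi_orthogonal
from pfanet.tasks import gen_conv_task
from pfanet.updates import TrainConfig

from conftest import loop_conv2d, relative_error


class TestForwardConv:
    def test_one_by_one_kernel_is_pixelwise_matmul(self, rng):
        x = rng.normal(size=(2, 3, 4, 4))
        K = rng.normal(size=(5, 3, 1, 1))
        out = conv_forward_raw(x, K)
        want = np.einsum("oc,bchw->bohw", K[:, :, 0, 0], x)
        assert np.allclose(out, want)

    def test_delta_kernel_same_padding_is_channel_mix(self, rng):
        x = rng.normal(size=(1, 2, 5, 5))
        K = np.zeros((3, 2, 3, 3))
        M = rng.normal(size=(3, 2))
        K[:, :, 1, 1] = M
        out = conv_forward_raw(x, K, pad=1)
        want = np.einsum("oc,bchw->bohw", M, x)
        assert np.allclose(out, want)

    @pytest.mark.parametrize("stride,pad,dil", [(1, 0, 1), (2, 1, 1), (1, 2, 2)])
    def test_matches_loop_oracle(self, rng, stride, pad, dil):
        x = rng.normal(size=(2, 3, 7, 6))
        K = rng.normal(size=(4, 3, 3, 3))
        out = conv_forward_raw(x, K, stride=stride, pad=pad, dil=dil)
        for b in range(2):
            want = loop_conv2d(x[b], K, stride=stride, pad=pad, dil=dil)
            assert relative_error(out[b], want) <= 1e-6

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(DimensionError):
            conv_forward_raw(rng.normal(size=(1, 2, 4, 4)),
                             rng.normal(size=(3, 5, 3, 3)))

    def test_groups_not_supported(self):
        with pytest.raises(DimensionError):
            ConvLayer(np.zeros((2, 2, 3, 3)), np.zeros(2), groups=2)


def small_conv_net(rng, in_ch=2, img=5, n_classes=3, channels=(3,)):
    return build_conv_network(img, in_ch, n_classes, conv_channels=channels,
                              rng=rng)


class TestBackwardConv:
    @pytest.mark.parametrize("seed", range(4))
    def test_bp_error_matches_finite_differences(self, seed):
        """Conv input-gradient errors equal -dL/dx_l numerically."""
        rng = np.random.default_rng(seed)
        net = small_conv_net(rng)
        x = rng.normal(size=(2, 2, 5, 5))
        y = rng.integers(0, 3, size=2)
        out = net.forward(x)
        loss, e_L = output_error(out, y)
        stack = backward(net, FeedbackState.for_network(net, "bp"), e_L)
        # finite differences on the conv layer's preactivation z_1 (the
        # error stack carries preactivation gradients, gated by sigma')
        z1 = net.layers[0].cached_pre
        eps = 1e-6
        fd = np.zeros_like(z1)
        for idx in np.ndindex(z1.shape):
            for sgn in (+1, -1):
                zp = z1.copy()
                zp[idx] += sgn * eps
                x1 = np.maximum(zp, 0.0)  # the conv layer is relu
                logits = x1.reshape(2, -1) @ net.layers[1].W.T + net.layers[1].b
                l_, _ = output_error(logits, y)
                fd[idx] -= sgn * l_ / (2 * eps)
        fd *= 2  # undo the batch-mean (batch of 2)
        assert relative_error(stack.e[1], fd) <= 1e-5
        assert np.isfinite(loss)

    def test_one_by_one_conv_error_equals_dense_error(self, rng):
        """A 1x1 stride-1 conv on 1x1 feature maps is a dense layer; the
        backward rules must coincide."""
        x = rng.normal(size=(3, 4, 1, 1))
        K = rng.normal(size=(5, 4, 1, 1))
        e_next = rng.normal(size=(3, 5, 1, 1))
        conv = ConvLayer(K, np.zeros(5), "identity")
        conv.forward(x)
        got = error_bp_conv(conv, e_next)
        want = e_next[:, :, 0, 0] @ K[:, :, 0, 0]
        assert np.allclose(got[:, :, 0, 0], want)

    def test_fa_kernel_equal_to_w_reproduces_bp(self, rng):
        conv = ConvLayer(rng.normal(size=(4, 2, 3, 3)), np.zeros(4), "relu",
                         padding=1)
        conv.forward(rng.normal(size=(2, 2, 6, 6)))
        e = rng.normal(size=(2, 4, 6, 6))
        assert np.allclose(error_fa_conv(conv, conv.W, e),
                           error_bp_conv(conv, e))

    @pytest.mark.parametrize("seed", range(3))
    def test_pfa_composition_oracle(self, seed):
        """The two-factor conv error equals the one-shot error through the
        composed effective kernel, to 1e-10."""
        rng = np.random.default_rng(seed)
        conv = ConvLayer(rng.normal(size=(4, 2, 3, 3)), np.zeros(4), "relu",
                         stride=2, padding=1)
        conv.forward(rng.normal(size=(2, 2, 7, 7)))
        e = rng.normal(size=(2, 4, 4, 4))
        B = rng.normal(size=(9, 4))
        R = rng.normal(size=(9, 2, 3, 3))
        e_bar, raw = error_pfa_conv(conv, B, R, e)
        K_eff = compose_path_conv(R, B)
        want = error_fa_conv(conv, K_eff, e)
        assert np.abs(raw - want).max() <= 1e-10
        assert e_bar.shape == (2, 9, 4, 4)

    def test_identity_channel_b_with_matched_r_is_bp(self, rng):
        conv = ConvLayer(rng.normal(size=(3, 2, 3, 3)), np.zeros(3), "relu",
                         padding=1)
        conv.forward(rng.normal(size=(1, 2, 5, 5)))
        e = rng.normal(size=(1, 3, 5, 5))
        B = np.eye(3)
        R = np.einsum("ki,ichw->kchw", B, conv.W)
        _, raw = error_pfa_conv(conv, B, R, e)
        assert np.allclose(raw, error_bp_conv(conv, e))


class TestConvUpdates:
    @pytest.mark.parametrize("seed", range(3))
    def test_weight_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        net = small_conv_net(rng)
        conv = net.layers[0]
        x = rng.normal(size=(2, 2, 5, 5))
        y = rng.integers(0, 3, size=2)
        out = net.forward(x)
        _, e_L = output_error(out, y)
        stack = backward(net, FeedbackState.for_network(net, "bp"), e_L)
        g = conv_weight_grad(conv.cached_input, stack.e[1], conv.W.shape,
                             conv.stride, conv.padding, conv.dilation)
        eps = 1e-6
        fd = np.zeros_like(conv.W)
        for idx in np.ndindex(conv.W.shape):
            orig = conv.W[idx]
            conv.W[idx] = orig + eps
            lp, _ = output_error(net.forward(x), y)
            conv.W[idx] = orig - eps
            lm, _ = output_error(net.forward(x), y)
            conv.W[idx] = orig
            fd[idx] = -(lp - lm) / (2 * eps)
        assert relative_error(g, fd) <= 1e-5

    def test_zero_error_pure_decay(self, rng):
        conv = ConvLayer(rng.normal(size=(3, 2, 3, 3)), np.zeros(3))
        conv.forward(rng.normal(size=(1, 2, 5, 5)))
        W0 = conv.W.copy()
        update_conv_W(conv, np.zeros((1, 3, 3, 3)), lr=0.1, decay=0.01)
        assert np.allclose(conv.W, 0.99 * W0)

    def test_one_by_one_update_reduces_to_dense(self, rng):
        x = rng.normal(size=(4, 3, 1, 1))
        K = rng.normal(size=(2, 3, 1, 1))
        conv = ConvLayer(K.copy(), np.zeros(2), "identity")
        conv.forward(x)
        e = rng.normal(size=(4, 2, 1, 1))
        update_conv_W(conv, e, lr=0.2, decay=0.0)
        dense = DenseLayer(K[:, :, 0, 0].copy(), np.zeros(2), "identity")
        dense.forward(x[:, :, 0, 0])
        from pfanet.updates import update_W
        update_W(dense, e[:, :, 0, 0], lr=0.2, decay=0.0)
        assert np.allclose(conv.W[:, :, 0, 0], dense.W)
        assert np.allclose(conv.b, dense.b)

    def test_update_r_matches_weight_grad_shape_and_mask(self, rng):
        conv = ConvLayer(rng.normal(size=(3, 2, 3, 3)), np.zeros(3),
                         padding=1)
        conv.forward(rng.normal(size=(2, 2, 5, 5)))
        R = rng.normal(size=(6, 2, 3, 3))
        mask = (rng.random(R.shape) > 0.5).astype(float)
        R = R * mask
        e_bar = rng.normal(size=(2, 6, 5, 5))
        R2 = update_conv_R(conv, R, e_bar, lr=0.1, decay=0.01, mask=mask)
        assert R2.shape == R.shape
        assert np.all(R2[mask == 0] == 0)


def test_conv_pfa_o_matched_tracks_bp_over_full_run():
    """Channel-semi-orthogonal B with matched R reproduces conv backprop's
    loss curve over an entire training run to 1e-6."""
    data = gen_conv_task(6, 1, 2, 300, seed=4)
    losses = {}
    for mode, r_init in (("bp", "random"), ("pfa_o", "matched")):
        cfg = TrainConfig(algorithm=mode, epochs=3, seed=2, lr=0.05,
                          expansion_ratio=3, r_init=r_init)
        net = build_conv_network(6, 1, 2, rng=seed_stream(2, "weights"))
        fb = FeedbackState.for_network(net, mode, cfg.expansion_ratio,
                                       rng=seed_stream(2, "feedback"),
                                       r_init=r_init)
        _, _, res = run_experiment(cfg, data, net=net, feedback=fb)
        losses[mode] = res.train_loss
    gap = max(abs(a - b) for a, b in zip(losses["bp"], losses["pfa_o"]))
    assert gap <= 1e-6
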