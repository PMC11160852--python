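"""Update-rule unit tests: decay exactness, outer-product structure, the
symmetric KP dynamics, the aligned-update identity, and mask enforcement."""

import dataclasses

import numpy as np
import pytest

from pfanet.core_net import DenseLayer
from pfanet.error_rules import FeedbackState, LayerFeedback
from pfanet.exceptions import DivergenceError, ModeError
from pfanet.randmat import init_semi_orthogonal
from pfanet.updates import (TrainConfig, apply_mask, update_R, update_W,
                            update_kp_feedback)

from conftest import random_dense_net


def make_layer(rng, n_out=3, n_in=4):
    layer = DenseLayer(rng.normal(size=(n_out, n_in)), rng.normal(size=n_out))
    layer.forward(rng.normal(size=(2, n_in)))
    return layer


class TestUpdateW:
    def test_zero_error_zero_decay_leaves_weights(self, rng):
        layer = make_layer(rng)
        W0, b0 = layer.W.copy(), layer.b.copy()
        update_W(layer, np.zeros((2, 3)), lr=0.1, decay=0.0)
        assert np.array_equal(layer.W, W0) and np.array_equal(layer.b, b0)

    def test_zero_error_pure_decay_shrinks_exactly(self, rng):
        layer = make_layer(rng)
        W0 = layer.W.copy()
        for _ in range(3):
            update_W(layer, np.zeros((2, 3)), lr=0.1, decay=0.01)
        assert np.allclose(layer.W, (1 - 0.01) ** 3 * W0)

    def test_rank_one_outer_product(self, rng):
        layer = make_layer(rng)
        W0 = layer.W.copy()
        x = np.zeros(4); x[2] = 1.0
        e = np.zeros(3); e[1] = 1.0
        update_W(layer, e, lr=0.25, decay=0.0, x_l=x)
        diff = layer.W - W0
        assert diff[1, 2] == pytest.approx(0.25)
        diff[1, 2] = 0.0
        assert np.all(diff == 0)

    def test_batch_mean_not_sum(self, rng):
        layer = make_layer(rng)
        W0 = layer.W.copy()
        e = np.ones((4, 3))
        x = np.ones((4, 4))
        update_W(layer, e, lr=0.1, decay=0.0, x_l=x)
        assert np.allclose(layer.W - W0, 0.1)  # mean over batch, not x4

    def test_nan_update_aborts(self, rng):
        layer = make_layer(rng)
        with pytest.raises(DivergenceError):
            update_W(layer, np.full((2, 3), np.nan), lr=0.1, decay=0.0)


class TestUpdateR:
    def _pfa_fb(self, rng, n_l=4, n_bar=6):
        fb = LayerFeedback(mode="pfa", B=rng.normal(size=(n_bar, 3)),
                           R=rng.normal(size=(n_l, n_bar)))
        return fb

    def test_rank_one(self, rng):
        fb = self._pfa_fb(rng)
        R0 = fb.R.copy()
        fb.e_bar = np.zeros((1, 6)); fb.e_bar[0, 5] = 1.0
        x = np.zeros((1, 4)); x[0, 1] = 1.0
        update_R(fb, x, lr=0.3, decay=0.0)
        diff = fb.R - R0
        assert diff[1, 5] == pytest.approx(0.3)
        diff[1, 5] = 0.0
        assert np.all(diff == 0)

    def test_zero_ebar_pure_decay(self, rng):
        fb = self._pfa_fb(rng)
        R0 = fb.R.copy()
        fb.e_bar = np.zeros((2, 6))
        update_R(fb, np.ones((2, 4)), lr=0.1, decay=0.05)
        assert np.allclose(fb.R, 0.95 * R0)

    def test_wrong_mode_rejected(self, rng):
        fb = LayerFeedback(mode="fa", B_fa=rng.normal(size=(4, 3)))
        with pytest.raises(ModeError):
            update_R(fb, np.ones((1, 4)), lr=0.1, decay=0.0)

    def test_requires_cached_intermediate_error(self, rng):
        fb = self._pfa_fb(rng)
        with pytest.raises(ModeError):
            update_R(fb, np.ones((1, 4)), lr=0.1, decay=0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_aligned_updates_with_semi_orthogonal_b(self, seed):
        """B^T (dR)^T equals dW when B^T B = I and the learning rates match:
        both sides computed independently on one random minibatch."""
        rng = np.random.default_rng(seed)
        n_l, n_next, n_bar = 5, 3, 9
        B = init_semi_orthogonal(n_bar, n_next, rng)
        x = rng.normal(size=(4, n_l))
        e_next = rng.normal(size=(4, n_next))
        eta = 0.1
        dW = eta * e_next.T @ x / 4
        e_bar = e_next @ B.T
        dR = eta * x.T @ e_bar / 4
        assert np.abs(B.T @ dR.T - dW).max() <= 1e-10


class TestKPDynamics:
    def test_matched_init_stays_symmetric_forever(self, rng):
        """With feedback initialized to W^T and shared lr/decay, the KP
        feedback equals W^T after every step, exactly."""
        net = random_dense_net(rng, sizes=[4, 3, 2])
        fb = FeedbackState.for_network(net, "kp", rng=0)
        lf = fb.layers[1]
        upper = net.layers[1]
        lf.R = upper.W.T.copy()
        for step in range(5):
            x = rng.normal(size=(3, 4))
            net.forward(x)
            e = rng.normal(size=(3, 2))
            x1 = upper.cached_input
            update_kp_feedback(lf, e, x1, lr=0.1, decay=0.01)
            update_W(upper, e, lr=0.1, decay=0.01)
            assert np.allclose(lf.R, upper.W.T, atol=1e-14)

    def test_asymmetry_decays_geometrically_under_pure_decay(self, rng):
        """Zero error stream: the W-vs-feedback difference shrinks by exactly
        (1 - gamma) per step (linear recursion D_{t+1} = (1-gamma) D_t)."""
        net = random_dense_net(rng, sizes=[4, 3, 2])
        fb = FeedbackState.for_network(net, "kp", rng=1)
        lf, upper = fb.layers[1], net.layers[1]
        net.forward(rng.normal(size=(2, 4)))
        gamma = 0.02
        d0 = np.linalg.norm(upper.W.T - lf.R)
        for t in range(1, 6):
            update_kp_feedback(lf, np.zeros((2, 2)), upper.cached_input,
                               lr=0.1, decay=gamma)
            update_W(upper, np.zeros((2, 2)), lr=0.1, decay=gamma)
            d = np.linalg.norm(upper.W.T - lf.R)
            assert d == pytest.approx((1 - gamma) ** t * d0, rel=1e-10)

    def test_kp_wrapper_rejects_other_modes(self, rng):
        fb = LayerFeedback(mode="pfa", B=np.eye(3), R=rng.normal(size=(4, 3)))
        with pytest.raises(ModeError):
            update_kp_feedback(fb, np.ones((1, 3)), np.ones((1, 4)), 0.1, 0.0)


class TestMasks:
    def test_all_ones_is_identity_and_all_zeros_annihilates(self, rng):
        M = rng.normal(size=(5, 5))
        assert np.array_equal(apply_mask(M, np.ones_like(M)), M)
        assert np.all(apply_mask(M, np.zeros_like(M)) == 0)

    def test_idempotent(self, rng):
        M = rng.normal(size=(6, 6))
        mask = (rng.random((6, 6)) > 0.5).astype(float)
        once = apply_mask(M, mask)
        assert np.array_equal(apply_mask(once, mask), once)

    def test_mask_density_within_binomial_bound(self):
        rng = np.random.default_rng(7)
        n = 10_000
        mask = (rng.random(n) >= 0.5).astype(float)
        p_hat = mask.mean()
        sigma = np.sqrt(0.25 / n)
        assert abs(p_hat - 0.5) <= 3 * sigma

    def test_masked_entries_stay_zero_after_training(self, rng):
        """Exhaustive check on a small trained net: every masked entry of
        B and R is exactly 0 after a full run."""
        import pfanet
        from pfanet.updates import TrainConfig
        data = pfanet.gen_teacher_task(8, 2, 300, seed=3)
        cfg = TrainConfig(algorithm="pfa", hidden_sizes=(10,), epochs=3,
                          sparsity=0.4, seed=5, expansion_ratio=3)
        _, fb, _ = pfanet.run_experiment(cfg, data)
        for lf in fb.layers.values():
            assert np.all(lf.B[lf.mask_B == 0] == 0)
            assert np.all(lf.R[lf.mask_R == 0] == 0)


class TestTrainConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(algorithm="nope")
        with pytest.raises(ValueError):
            TrainConfig(sparsity=1.0)
        with pytest.raises(ValueError):
            TrainConfig(expansion_ratio=0.5)
        with pytest.raises(ValueError):
            TrainConfig(wd_main=1.0)

    def test_two_phase_decay_schedule(self):
        cfg = TrainConfig(wd_initial=1e-2, wd_main=1e-4, wd_initial_epochs=2)
        assert cfg.decay_at(1) == cfg.decay_at(2) == 1e-2
        assert cfg.decay_at(3) == 1e-4

    def test_yaml_round_trip(self, tmp_path):
        cfg = TrainConfig(algorithm="sf", lr=0.7, hidden_sizes=(12, 3),
                          sparsity=0.25)
        path = tmp_path / "cfg.yaml"
        cfg.to_file(path)
        assert TrainConfig.from_file(path) == cfg

    def test_lr_r_defaults_to_lr(self):
        assert TrainConfig(lr=0.3).effective_lr_r == 0.3
        assert TrainConfig(lr=0.3, lr_r=0.0).effective_lr_r == 0.0

    def test_replace_keeps_validation(self):
        cfg = TrainConfig()
        with pytest.raises(ValueError):
            dataclasses.replace(cfg, algorithm="bogus")
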