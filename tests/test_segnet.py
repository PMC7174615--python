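import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from headgrade.segnet import (ImprovedResNetModel, ModelConfig, TrainSchedule,
                              build_model, dice_loss, load_checkpoint,
                              lrelu_softplus, predict_mask, relu,
                              residual_block_forward, save_checkpoint,
                              train_arrays)
from headgrade.segnet.model import dice_loss_grad
from headgrade.segnet.train import learning_rate_at

TINY = ModelConfig(stage_widths=(4, 4, 8, 8), head_widths=(8, 4, 1),
                   fusion_channels=4, dropout_rate=0.0, input_size=32)


class TestActivations:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (-5.0, 0.0), (3.2, 3.2)])
    def test_relu(self, x, expected):
        assert relu(x) == expected

    def test_lrelu_softplus_reference_points(self):
        assert lrelu_softplus(0.0) == pytest.approx(0.0, abs=1e-12)
        assert lrelu_softplus(-1.0) == pytest.approx(-0.01)
        assert lrelu_softplus(10.0) == pytest.approx(
            10 + np.log1p(np.exp(-10)) - np.log(2), abs=1e-12)

    def test_continuity_at_zero(self):
        for eps in (1e-3, 1e-6, 1e-9):
            assert abs(lrelu_softplus(eps) - lrelu_softplus(-eps)) < 2 * eps

    def test_monotone_on_grid(self):
        x = np.linspace(-50, 50, 1001)
        y = lrelu_softplus(x)
        assert (np.diff(y) >= 0).all()

    def test_linear_asymptote(self):
        for x in (20.0, 100.0, 700.0):
            assert abs(lrelu_softplus(x) - (x - np.log(2))) < 1e-8

    def test_no_overflow_for_large_inputs(self):
        assert np.isfinite(lrelu_softplus(1e4))

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6))
    def test_monotone_for_arbitrary_pairs(self, a, b):
        lo, hi = sorted((a, b))
        assert lrelu_softplus(lo) <= lrelu_softplus(hi) + 1e-12


def brute_conv_same(x, w):
    """Naive loops: stride-1 'same' convolution, x (C,H,W), w (O,C,k,k)."""
    o, c, k, _ = w.shape
    p = k // 2
    h, wd = x.shape[1:]
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    out = np.zeros((o, h, wd))
    for oc in range(o):
        for r in range(h):
            for cc in range(wd):
                out[oc, r, cc] = (xp[:, r:r + k, cc:cc + k] * w[oc]).sum()
    return out


class TestResidualBlock:
    def test_zero_weights_identity_skip(self):
        x = np.random.default_rng(0).normal(size=(3, 4, 4))
        w1 = np.zeros((3, 3, 3, 3))
        w2 = np.zeros((3, 3, 3, 3))
        np.testing.assert_allclose(residual_block_forward(x, w1, w2), x)

    def test_zero_input_zero_output(self):
        rng = np.random.default_rng(1)
        w1 = rng.normal(size=(4, 2, 3, 3))
        w2 = rng.normal(size=(2, 4, 3, 3))
        ws = rng.normal(size=(2, 2))
        out = residual_block_forward(np.zeros((2, 5, 5)), w1, w2, ws)
        np.testing.assert_allclose(out, 0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cin, cmid = int(rng.integers(1, 5)), int(rng.integers(1, 5))
        h, w = int(rng.integers(3, 9)), int(rng.integers(3, 9))
        x = rng.normal(size=(cin, h, w))
        w1 = rng.normal(size=(cmid, cin, 3, 3))
        w2 = rng.normal(size=(cin, cmid, 3, 3))
        expected = brute_conv_same(np.maximum(brute_conv_same(x, w1), 0), w2) + x
        np.testing.assert_allclose(residual_block_forward(x, w1, w2), expected)

    def test_channel_mismatch_needs_projection(self):
        x = np.zeros((2, 4, 4))
        w1 = np.zeros((3, 2, 3, 3))
        w2 = np.zeros((3, 3, 3, 3))
        with pytest.raises(ValueError):
            residual_block_forward(x, w1, w2, Ws=None)


class TestDiceLoss:
    def test_perfect_overlap_near_zero(self):
        mask = np.zeros((32, 32))
        mask[5:20, 5:20] = 1.0
        assert mask.sum() >= 100
        assert dice_loss(mask, mask) < 1e-3

    def test_total_mismatch_value(self):
        prob = np.ones((32, 32))
        target = np.zeros((32, 32))
        assert dice_loss(prob, target) == pytest.approx(1024 / 1025)

    def test_range_bound(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.random((8, 8))
            t = (rng.random((8, 8)) > 0.5).astype(float)
            assert 0.0 <= dice_loss(p, t) <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 4)), np.zeros((4, 5)))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, (5, 5))
        t = (rng.random((5, 5)) > 0.5).astype(float)
        g = dice_loss_grad(p, t)
        eps = 1e-6
        for idx in [(0, 0), (2, 3), (4, 4)]:
            p2 = p.copy()
            p2[idx] += eps
            fd = (dice_loss(p2, t) - dice_loss(p, t)) / eps
            assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestModel:
    def test_build_deterministic_param_count(self):
        a = build_model(TINY, seed=1)
        b = build_model(TINY, seed=2)
        assert a.n_params() == b.n_params()
        assert a.n_params() > 0

    def test_forward_shape_and_range(self):
        model = build_model(TINY, seed=0)
        x = np.random.default_rng(0).integers(0, 256, (1, 32, 32, 3))
        prob = model.forward(x, train=False)
        assert prob.shape == (1, 32, 32)
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_one_hot_fusion_ignores_other_branches(self):
        model = build_model(TINY, seed=0)
        model.fusion_w.value[:] = [60.0, 0.0, 0.0, 0.0]
        x = np.random.default_rng(1).integers(0, 256, (1, 32, 32, 3))
        before = model.forward(x, train=False)
        model.branches[3].W.value += 10.0  # perturb an ignored branch
        model.branches[2].W.value -= 5.0
        after = model.forward(x, train=False)
        np.testing.assert_allclose(after, before, atol=1e-9)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(stage_widths=(8, 16, 32))
        with pytest.raises(ValueError):
            ModelConfig(head_widths=(8, 4, 2))
        with pytest.raises(ValueError):
            ModelConfig(input_size=30)  # not divisible by the total stride


class TestTraining:
    def _data(self, n=8):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 256, (n, 32, 32, 3))
        Y = np.zeros((n, 32, 32))
        Y[:, 8:24, 8:24] = 1.0
        return X, Y

    def test_one_epoch_reduces_loss(self):
        X, Y = self._data()
        model = build_model(TINY, seed=0)
        init_loss = dice_loss(model.forward(X, train=False), Y)
        sched = TrainSchedule(base_lr=0.1, second_lr=0.05, epochs=2,
                              batch_size=4, seed=0)
        hist = train_arrays(model, X, Y, schedule=sched)
        assert hist["train_loss"][-1] < init_loss

    def test_identical_seed_identical_history(self):
        X, Y = self._data()
        sched = TrainSchedule(base_lr=0.1, second_lr=0.05, epochs=2,
                              batch_size=4, seed=5)
        h1 = train_arrays(build_model(TINY, seed=3), X, Y, schedule=sched)
        h2 = train_arrays(build_model(TINY, seed=3), X, Y, schedule=sched)
        assert h1["train_loss"] == h2["train_loss"]

    def test_lr_switch_recorded_in_history(self):
        X, Y = self._data()
        sched = TrainSchedule(base_lr=0.01, second_lr=0.005, switch_iteration=3,
                              epochs=3, batch_size=4, seed=0)
        hist = train_arrays(build_model(TINY, seed=0), X, Y, schedule=sched)
        assert hist["lr"][:3] == [0.01] * 3
        assert all(lr == 0.005 for lr in hist["lr"][3:])

    def test_reference_schedule_constants(self):
        sched = TrainSchedule()
        assert (sched.base_lr, sched.second_lr) == (0.001, 0.0005)
        assert sched.momentum == 0.9
        assert learning_rate_at(sched, 2999) == 0.001
        assert learning_rate_at(sched, 3000) == 0.0005

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_arrays(build_model(TINY, seed=0), np.zeros((0, 32, 32, 3)),
                         np.zeros((0, 32, 32)))


class _StubModel:
    """Constant-probability model for threshold-behavior tests."""

    def __init__(self, p, size=32):
        self.config = ModelConfig(stage_widths=(4, 4, 8, 8), head_widths=(8, 4, 1),
                                  fusion_channels=4, input_size=size)
        self.p = p

    def forward(self, x, train=False):
        return np.full(x.shape[:3], self.p)


class TestPredictMask:
    def test_constant_stub_thresholding(self):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        assert (predict_mask(_StubModel(0.7), img, 0.5) == 1).all()
        assert (predict_mask(_StubModel(0.7), img, 0.9) == 0).all()

    def test_tiled_agrees_with_direct_on_larger_image(self):
        model = build_model(TINY, seed=0)
        img = np.random.default_rng(2).integers(0, 256, (32, 64, 3)).astype(np.uint8)
        tiled = predict_mask(model, img, 0.5)
        direct = (model.forward(img[None].astype(float), train=False)[0] > 0.5)
        assert tiled.shape == (32, 64)
        # tiles only differ from the full pass near tile borders
        assert (tiled == direct).mean() > 0.95

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            predict_mask(_StubModel(0.5), np.zeros((32, 32, 3)), 1.5)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        model = build_model(TINY, seed=4)
        x = np.random.default_rng(3).integers(0, 256, (1, 32, 32, 3))
        before = model.forward(x, train=False)
        path = tmp_path / "m.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        np.testing.assert_allclose(back.forward(x, train=False), before)
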