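"""Network architecture, gradients, augmentations and the training loop."""

import numpy as np
import pytest

from geodose.nn import (
    AugmentConfig,
    NetConfig,
    TrainConfig,
    build_model,
    load_model,
    save_model,
)
from geodose.nn.train import (
    TrainingCase,
    augment_case,
    central_slice_loss,
    predict,
    train,
)


@pytest.fixture()
def tiny_cfg():
    return NetConfig(levels=2, base_features=2, input_dims=(8, 8, 4),
                     dropblock_rate=0.0)


@pytest.fixture()
def tiny_model(tiny_cfg):
    return build_model(tiny_cfg, seed=0)


class TestArchitecture:
    def test_default_level_widths_double(self):
        cfg = NetConfig()
        assert cfg.level_widths == [24, 48, 96, 192]
        assert cfg.groups == 6  # largest divisor of 24 not exceeding 8

    def test_channel_audit_of_built_graph(self):
        cfg = NetConfig(levels=3, base_features=8, input_dims=(16, 16, 8))
        m = build_model(cfg)
        enc_widths = [b.features for b in m.enc_blocks]
        assert enc_widths == [8, 16, 32]
        # encoder block input channels: 1, then 2x previous width (dual pool)
        assert [b.ops[0].w.value.shape[1] for b in m.enc_blocks] == [1, 16, 32]
        # decoder inputs: 2x lower width (dual upsample) + same-level skip
        assert [b.ops[0].w.value.shape[1] for b in m.dec_blocks] == [
            2 * 32 + 16, 2 * 16 + 8
        ]
        assert [b.features for b in m.dec_blocks] == [16, 8]
        # every block: conv, crelu-conv, conv, crelu-conv, then group norm
        kinds = [type(op).__name__ for op in m.enc_blocks[0].ops]
        assert kinds == ["Conv3d", "CReLU", "Conv3d", "Conv3d", "CReLU",
                        "Conv3d", "GroupNorm"]
        assert m.head.w.value.shape[:2] == (1, 8)

    def test_indivisible_input_dims_rejected_at_build(self):
        with pytest.raises(ValueError, match="divisible"):
            NetConfig(levels=4, base_features=8, input_dims=(20, 20, 8))

    def test_forward_shape_and_finiteness(self, tiny_model):
        out = tiny_model.forward(np.zeros((2, 1, 4, 8, 8)))
        assert out.shape == (2, 1, 4, 8, 8)
        assert np.all(np.isfinite(out))

    def test_eval_mode_deterministic_despite_dropblock(self):
        cfg = NetConfig(levels=2, base_features=4, input_dims=(8, 8, 4),
                        dropblock_rate=0.3)
        m = build_model(cfg, seed=1)
        m.head.w.value[:] = 1.0  # head starts at zero; open it for this check
        x = np.random.default_rng(0).standard_normal((1, 1, 4, 8, 8))
        np.testing.assert_array_equal(m.forward(x), m.forward(x))
        # training mode with dropblock actually perturbs activations
        assert not np.array_equal(m.forward(x, training=True),
                                  m.forward(x, training=True))


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_model):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 1, 4, 8, 8))
        t = rng.standard_normal((2, 4, 8, 8))
        m = tiny_model
        m.zero_grad()
        pred = m.forward(x)
        _, dpred = central_slice_loss(pred, t)
        m.backward(dpred)
        eps = 1e-6
        picker = np.random.default_rng(2)
        for p in m.params():
            flat = p.value.ravel()
            for _ in range(3):
                i = picker.integers(flat.size)
                old = flat[i]
                flat[i] = old + eps
                lp = central_slice_loss(m.forward(x), t)[0]
                flat[i] = old - eps
                lm = central_slice_loss(m.forward(x), t)[0]
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = p.grad.ravel()[i]
                assert abs(num - ana) <= 1e-6 + 1e-4 * (abs(num) + abs(ana)), \
                    f"{p.name}: numeric {num} vs analytic {ana}"

    def test_gradient_flows_only_through_central_slice(self, tiny_model):
        """Changing the target off the supervised slice changes no gradient."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal((1, 1, 4, 8, 8))
        t = rng.standard_normal((1, 4, 8, 8))
        m = tiny_model

        def grads_for(target):
            m.zero_grad()
            pred = m.forward(x)
            _, dpred = central_slice_loss(pred, target)
            m.backward(dpred)
            return [p.grad.copy() for p in m.params()]

        g1 = grads_for(t)
        t_off = t.copy()
        t_off[:, 0] += 100.0  # off-slice change only (central slice is z=2)
        t_off[:, 3] -= 50.0
        g2 = grads_for(t_off)
        for a, b in zip(g1, g2):
            np.testing.assert_array_equal(a, b)


class TestAugmentation:
    @pytest.fixture()
    def case(self, rng):
        x = rng.random((4, 8, 8))
        painted = np.zeros_like(x, dtype=bool)
        painted[:, 0, :] = True
        return TrainingCase(x=x, target=rng.random((4, 8, 8)),
                            painted_mask=painted)

    def test_zero_factor_kills_fluence_and_dose_keeps_red(self, case):
        cfg = AugmentConfig(scale_range=(0.0, 0.0), rotate=False)
        out = augment_case(case, cfg, 0)
        np.testing.assert_array_equal(out.x[case.painted_mask], 0.0)
        np.testing.assert_array_equal(out.x[~case.painted_mask],
                                      case.x[~case.painted_mask])
        np.testing.assert_array_equal(out.target, 0.0)

    def test_factor_two_doubles_fluence_and_dose(self, case):
        cfg = AugmentConfig(scale_range=(2.0, 2.0), rotate=False)
        out = augment_case(case, cfg, 0)
        np.testing.assert_allclose(out.x[case.painted_mask],
                                   2.0 * case.x[case.painted_mask])
        np.testing.assert_allclose(out.target, 2.0 * case.target)

    def test_full_turn_rotation_is_identity_within_interp(self, case):
        cfg = AugmentConfig(scale_range=(1.0, 1.0), rotate=True,
                            rotation_range=(360.0, 360.0))
        out = augment_case(case, cfg, 0)
        assert np.abs(out.x - case.x).max() < 0.01 * np.abs(case.x).max()

    def test_missing_painted_mask_rejected(self, case):
        bad = TrainingCase(x=case.x, target=case.target, painted_mask=None)
        with pytest.raises(ValueError, match="painted"):
            augment_case(bad, AugmentConfig(), 0)


def _linear_cases(n, rng, shape=(4, 8, 8)):
    """Cases with dose = blurred scalar multiple of a painted border ring."""
    from scipy import ndimage
    cases = []
    for _ in range(n):
        painted = np.zeros(shape, dtype=bool)
        painted[:, 0, :] = True
        amp = rng.uniform(0.5, 2.0)
        x = np.where(painted, amp, rng.uniform(0.9, 1.1))
        target = ndimage.gaussian_filter(np.full(shape, amp), 1.0)
        cases.append(TrainingCase(x=x, target=target, painted_mask=painted))
    return cases


class TestTraining:
    def test_loss_decreases_on_learnable_toy_problem(self, rng):
        cfg = NetConfig(levels=2, base_features=4, input_dims=(8, 8, 4),
                        dropblock_rate=0.0)
        m = build_model(cfg, seed=0)
        cases = _linear_cases(8, rng)
        tcfg = TrainConfig(lr=1e-3, batch=4, patience=50, max_epochs=30, seed=0)
        m, hist = train(m, cases[:6], cases[6:], tcfg, aug=None)
        assert hist["val_loss"][-1] < hist["val_loss"][0]
        assert hist["best_val_loss"] <= min(hist["val_loss"]) + 1e-12

    def test_fixed_seed_reproduces_loss_history(self, rng):
        cfg = NetConfig(levels=2, base_features=2, input_dims=(8, 8, 4),
                        dropblock_rate=0.1, dropblock_size=3)
        cases = _linear_cases(6, rng)
        aug = AugmentConfig(scale_range=(0.5, 1.5), rotate=False)
        hists = []
        for _ in range(2):
            m = build_model(cfg, seed=4)
            tcfg = TrainConfig(lr=1e-3, batch=2, patience=10, max_epochs=5,
                               seed=9)
            _, h = train(m, cases[:4], cases[4:], tcfg, aug)
            hists.append(h)
        assert hists[0]["train_loss"] == hists[1]["train_loss"]
        assert hists[0]["val_loss"] == hists[1]["val_loss"]

    def test_patience_halts_on_plateau(self, rng):
        # lr=0 gives a perfectly flat validation loss: epoch 0 is best and
        # training stops after exactly `patience` further epochs
        cfg = NetConfig(levels=2, base_features=2, input_dims=(8, 8, 4),
                        dropblock_rate=0.0)
        m = build_model(cfg, seed=0)
        cases = _linear_cases(4, rng)
        tcfg = TrainConfig(lr=1e-30, batch=2, patience=1, max_epochs=50, seed=0)
        _, hist = train(m, cases[:3], cases[3:], tcfg, aug=None)
        assert len(hist["val_loss"]) == 2  # plateau epoch + 1

    def test_empty_split_rejected(self, tiny_model, rng):
        cases = _linear_cases(2, rng)
        with pytest.raises(ValueError, match="empty training"):
            train(tiny_model, [], cases, TrainConfig(), None)
        with pytest.raises(ValueError, match="empty validation"):
            train(tiny_model, cases, [], TrainConfig(), None)


class TestPredictAndCheckpoint:
    def test_same_input_same_output(self, tiny_model):
        x = np.random.default_rng(0).random((4, 8, 8))
        np.testing.assert_array_equal(predict(tiny_model, x),
                                      predict(tiny_model, x))

    def test_spacing_mismatch_rejected(self, tiny_model):
        tiny_model.meta["spacing"] = (2.7, 2.7, 3.0)
        x = np.zeros((4, 8, 8))
        with pytest.raises(ValueError, match="spacing"):
            predict(tiny_model, x, spacing=(2.0, 2.0, 3.0))

    def test_wrong_dims_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="dims"):
            predict(tiny_model, np.zeros((4, 8, 10)))

    def test_checkpoint_round_trip(self, tiny_model, tmp_path, rng):
        tiny_model.meta["dose_scale"] = 45.0
        tiny_model.meta["spacing"] = (20.0, 20.0, 10.0)
        f = tmp_path / "model.npz"
        save_model(tiny_model, f)
        loaded = load_model(f)
        x = rng.random((4, 8, 8))
        np.testing.assert_allclose(predict(loaded, x), predict(tiny_model, x))
        assert loaded.meta["dose_scale"] == 45.0
        assert tuple(loaded.meta["spacing"]) == (20.0, 20.0, 10.0)
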