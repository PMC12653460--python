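"""Network architecture, loss, gradients, and training behaviour."""

import numpy as np
import pytest

from octcalc.segnet import (
    NetConfig,
    TrainConfig,
    UNetSegmenter,
    build_network,
    combined_loss,
)
from octcalc.segnet.estimator import check_no_leakage


def parameter_count_oracle(in_channels, n_classes, base, depth):
    """Layer-by-layer enumeration of (kh*kw*cin + 1)*cout, written from
    the architecture definition alone, independent of the build."""
    convs = []
    cin = in_channels
    filters = [base * 2**k for k in range(depth)]
    for f in filters:  # encoder: two 3x3 convs per block
        convs.append((3, 3, cin, f))
        convs.append((3, 3, f, f))
        cin = f
    bottleneck = base * 2**depth
    convs.append((3, 3, filters[-1], bottleneck))
    convs.append((3, 3, bottleneck, bottleneck))
    cup = bottleneck
    for f in reversed(filters):  # decoder: one 3x3 conv after concat
        convs.append((3, 3, cup + f, f))
        cup = f
    convs.append((1, 1, cup, n_classes))  # 1x1 head
    return sum((kh * kw * ci + 1) * co for kh, kw, ci, co in convs)


class TestArchitecture:
    def test_shape_contract(self):
        net = build_network(NetConfig(base_filters=4), seed=0)
        x = np.zeros((1, 2, 256, 480), dtype=np.float32)
        # full-size pass is heavy; use the smallest grid with the same
        # divisibility for the probability check and the full grid once
        probs = net.forward(np.zeros((1, 2, 32, 48), dtype=np.float32))
        assert probs.shape == (1, 10, 32, 48)

    def test_encoder_filter_doubling(self):
        cfg = NetConfig()
        assert cfg.encoder_filters == (16, 32, 64, 128)
        net = build_network(cfg, seed=0)
        for k, f in enumerate((16, 32, 64, 128)):
            assert net.params[f"enc{k}a_w"].shape[0] == f
            assert net.params[f"enc{k}b_w"].shape == (f, f, 3, 3)

    @pytest.mark.parametrize("base,depth", [(16, 4), (4, 4), (8, 3)])
    def test_parameter_count_matches_enumeration_oracle(self, base, depth):
        expected = parameter_count_oracle(2, 10, base, depth)
        net = build_network(NetConfig(base_filters=base, depth=depth), seed=0)
        assert net.n_parameters == expected

    def test_indivisible_input_rejected(self):
        net = build_network(NetConfig(base_filters=2), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 2, 30, 48), dtype=np.float32))

    def test_output_is_probability_simplex(self, rng):
        net = build_network(NetConfig(base_filters=4), seed=1)
        x = rng.standard_normal((2, 2, 32, 32)).astype(np.float32)
        probs = net.forward(x)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)


class TestLoss:
    def test_one_hot_prediction_has_zero_dice_term(self):
        target = np.array([[[0, 1], [2, 3]]])
        probs = np.zeros((1, 10, 2, 2))
        np.put_along_axis(probs, target[:, None], 1.0, axis=1)
        dice_only = combined_loss(probs, target, ce_dice_mix=0.0)
        assert dice_only == pytest.approx(0.0, abs=1e-6)

    def test_uniform_prediction_ce_is_log_10(self):
        target = np.zeros((1, 4, 4), dtype=int)
        probs = np.full((1, 10, 4, 4), 0.1)
        ce_only = combined_loss(probs, target, ce_dice_mix=1.0)
        assert ce_only == pytest.approx(np.log(10), rel=1e-9)

    def test_matches_per_pixel_summation_oracle(self, rng):
        # Hand-rolled loops over pixels and classes.
        probs = rng.dirichlet(np.ones(10), size=(1, 4, 4)).transpose(0, 3, 1, 2)
        target = rng.integers(0, 10, (1, 4, 4))
        w = rng.uniform(0.5, 2.0, 10)
        mix, eps = 0.3, 1e-7
        ce_sum = wsum = 0.0
        for i in range(4):
            for j in range(4):
                t = target[0, i, j]
                ce_sum += w[t] * -np.log(probs[0, t, i, j])
                wsum += w[t]
        dice_num = np.zeros(10)
        dice_den = np.zeros(10)
        for c in range(10):
            for i in range(4):
                for j in range(4):
                    t = 1.0 if target[0, i, j] == c else 0.0
                    dice_num[c] += 2 * probs[0, c, i, j] * t
                    dice_den[c] += probs[0, c, i, j] + t
        dice = ((dice_num + eps) / (dice_den + eps) * w).sum() / w.sum()
        expected = mix * ce_sum / wsum + (1 - mix) * (1 - dice)
        got = combined_loss(probs, target, class_weights=w, ce_dice_mix=mix)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combined_loss(np.zeros((1, 10, 4, 4)), np.zeros((1, 3, 3), dtype=int))

    def test_gradient_matches_finite_differences(self, rng):
        # End-to-end check through softmax, conv, pool, upsample, concat.
        cfg = NetConfig(base_filters=2, dropout_rate=0.0)
        net = build_network(cfg, seed=0)
        for k in net.params:
            net.params[k] = net.params[k].astype(np.float64)
        x = rng.standard_normal((1, 2, 16, 16))
        y = rng.integers(0, 10, (1, 16, 16))
        w = np.ones(10)
        w[[5, 6, 7]] = 5.0

        def run():
            probs = net.forward(x)
            return combined_loss(probs, y, class_weights=w, return_grad=True)

        _, dlogits = run()
        grads = net.backward(dlogits)
        for name in ["enc0a_w", "botA_w", "dec2_w", "head_w"]:
            p = net.params[name]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps = 1e-6
            orig = p[idx]
            p[idx] = orig + eps
            up, _ = run()
            p[idx] = orig - eps
            down, _ = run()
            p[idx] = orig
            num = (up - down) / (2 * eps)
            assert grads[name][idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


def tiny_dataset(n_pullbacks=2, n_frames=2, hw=(32, 32), seed=0):
    rng = np.random.default_rng(seed)
    n = n_pullbacks * n_frames
    X = rng.uniform(-1, 1, (n, 2, *hw)).astype(np.float32)
    y = rng.integers(0, 10, (n, *hw))
    groups = np.repeat(np.arange(n_pullbacks), n_frames)
    return X, y, groups


class TestTraining:
    def test_one_epoch_smoke_emits_history_row(self):
        X, y, groups = tiny_dataset()
        est = UNetSegmenter(base_filters=2, epochs=1, batch_size=2, seed=0)
        est.fit(X, y, groups=groups)
        assert len(est.history_) == 1
        assert {"epoch", "train_loss", "val_loss", "val_plaque_dice"} <= set(
            est.history_[0]
        )
        assert est.predict(X[:1]).shape == (1, 32, 32)

    def test_loss_decreases_on_learnable_phantoms(self):
        # Structured frames (class depends on position+intensity) so the
        # network has something to learn in a few epochs.
        from octcalc.phantom import generate_pullback, random_phantom_config
        from octcalc.preprocess import PolarPreprocessor

        pre = PolarPreprocessor(radial_res_mm=0.03)
        Xs, ys, groups = [], [], []
        for pb in range(4):
            cfg = random_phantom_config(
                seed=300 + pb, n_frames=5, n_alines=48, n_samples=48,
                radial_res_mm=0.03, lumen_radius_mm=0.4,
                thickness_range_mm=(0.2, 0.5), arc_range_deg=(60, 140),
            )
            img, lab = generate_pullback(cfg)
            Xs.append(pre.transform(img.frames))
            ys.append(lab.classes)
            groups += [pb] * 5
        X = np.concatenate(Xs)
        y = np.concatenate(ys).astype(np.int64)
        est = UNetSegmenter(base_filters=8, epochs=6, batch_size=4, seed=1)
        est.fit(X, y, groups=np.array(groups))
        assert est.history_[-1]["train_loss"] < est.history_[0]["train_loss"]

    def test_same_seed_same_first_epoch_loss(self):
        X, y, groups = tiny_dataset(seed=3)
        losses = []
        for _ in range(2):
            est = UNetSegmenter(base_filters=2, epochs=1, batch_size=2, seed=5)
            est.fit(X, y, groups=groups)
            losses.append(est.history_[0]["train_loss"])
        assert losses[0] == losses[1]

    def test_pullback_leakage_is_hard_error(self):
        X, y, groups = tiny_dataset()
        est = UNetSegmenter(base_filters=2, epochs=1, seed=0)
        with pytest.raises(ValueError, match="both train and validation"):
            est.fit(X, y, groups=groups, X_val=X, y_val=y, groups_val=groups)
        with pytest.raises(ValueError):
            check_no_leakage([1, 2], [2, 3])

    def test_empty_dataset_rejected(self):
        est = UNetSegmenter(base_filters=2, epochs=1, seed=0)
        with pytest.raises(ValueError):
            est.fit(np.zeros((0, 2, 16, 16)), np.zeros((0, 16, 16), dtype=int))

    def test_checkpoint_round_trip(self, tmp_path):
        X, y, groups = tiny_dataset()
        est = UNetSegmenter(base_filters=2, epochs=1, batch_size=2, seed=0)
        est.fit(X, y, groups=groups)
        path = tmp_path / "model.npz"
        est.save(str(path))
        loaded = UNetSegmenter.load(str(path))
        np.testing.assert_allclose(loaded.predict_proba(X[:2]), est.predict_proba(X[:2]))


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(ce_dice_mix=1.5)
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
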