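"""FUnet fusion segmenter: losses vs brute-force oracles, architecture contracts."""

import math

import numpy as np
import pytest

from maefew import nn
from maefew.funet import (
    FusionBlock,
    FusionConfig,
    HybridLossParams,
    MAEDirect,
    MAEFUnet,
    dice_loss,
    focal_loss,
    hybrid_loss,
    pixel_cross_entropy,
    train_segmenter,
)
from maefew.nn import Tensor

RNG = np.random.default_rng(3)


def _random_case(n=2, c=3, h=8, w=8, seed=0):
    rng = np.random.default_rng(seed)
    logits = rng.normal(size=(n, c, h, w))
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs = e / e.sum(axis=1, keepdims=True)
    targets = rng.integers(0, c, size=(n, h, w))
    return probs, targets


def brute_dice(probs, targets, eps=1e-5):
    n, c, h, w = probs.shape
    total = 0.0
    for i in range(n):
        for k in range(c):
            num = den_p = den_g = 0.0
            for y in range(h):
                for x in range(w):
                    p = probs[i, k, y, x]
                    g = 1.0 if targets[i, y, x] == k else 0.0
                    num += p * g
                    den_p += p * p
                    den_g += g * g
            total += 1.0 - (2 * num + eps) / (den_p + den_g + eps)
    return total / (n * c)


def brute_focal(probs, targets, gamma=2.0, alpha=0.25):
    n, c, h, w = probs.shape
    vals = []
    for i in range(n):
        for y in range(h):
            for x in range(w):
                p = max(probs[i, targets[i, y, x], y, x], 1e-12)
                vals.append(-alpha * (1 - p) ** gamma * math.log(p))
    return float(np.mean(vals))


def brute_ce(probs, targets):
    n, c, h, w = probs.shape
    vals = []
    for i in range(n):
        for y in range(h):
            for x in range(w):
                p = max(probs[i, targets[i, y, x], y, x], 1e-12)
                vals.append(-math.log(p))
    return float(np.mean(vals))


class TestLossOracles:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dice_matches_brute_force(self, seed):
        probs, targets = _random_case(seed=seed)
        assert dice_loss(probs, targets).item() == pytest.approx(
            brute_dice(probs, targets), abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_focal_matches_brute_force(self, seed):
        probs, targets = _random_case(seed=seed)
        assert focal_loss(probs, targets).item() == pytest.approx(
            brute_focal(probs, targets), abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ce_matches_brute_force(self, seed):
        probs, targets = _random_case(seed=seed)
        assert pixel_cross_entropy(probs, targets).item() == pytest.approx(
            brute_ce(probs, targets), abs=1e-6)

    def test_dice_hand_case_two_pixels(self):
        # p = (0.8, 0.2) and (0.6, 0.4); both pixels truly class 0
        probs = np.array([[[[0.8, 0.6]], [[0.2, 0.4]]]])
        targets = np.array([[[0, 0]]])
        num0, den0 = 2 * (0.8 + 0.6) + 1e-5, (0.64 + 0.36) + 2 + 1e-5
        num1, den1 = 2 * 0.0 + 1e-5, (0.04 + 0.16) + 0 + 1e-5
        expected = 1 - 0.5 * (num0 / den0 + num1 / den1)
        assert dice_loss(probs, targets).item() == pytest.approx(expected, abs=1e-6)

    def test_focal_hand_value_at_half(self):
        probs = np.array([[[[0.5]], [[0.5]]]])
        targets = np.array([[[0]]])
        assert focal_loss(probs, targets).item() == pytest.approx(
            0.25 * 0.25 * np.log(2), abs=1e-6)

    def test_perfect_prediction_limits(self):
        targets = np.array([[[0, 1], [1, 0]]])
        probs = np.moveaxis(np.eye(2)[targets], -1, 1).astype(float)
        assert dice_loss(probs, targets).item() <= 1e-4
        assert focal_loss(probs, targets).item() == pytest.approx(0, abs=1e-9)
        assert hybrid_loss(probs, targets).item() <= 1e-3

    def test_disjoint_hard_prediction(self):
        targets = np.zeros((1, 2, 2), dtype=int)
        probs = np.zeros((1, 2, 2, 2))
        probs[:, 1] = 1.0  # predicts class 1 everywhere
        assert dice_loss(probs, targets).item() >= 1 - 1e-4

    def test_focal_decreases_with_gamma(self):
        probs, targets = _random_case(seed=4)
        losses = [focal_loss(probs, targets, gamma=g).item() for g in (0, 1, 2, 4)]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_hybrid_is_sum_of_components(self):
        probs, targets = _random_case(seed=5)
        total = hybrid_loss(probs, targets).item()
        parts = (dice_loss(probs, targets).item()
                 + focal_loss(probs, targets).item()
                 + pixel_cross_entropy(probs, targets).item())
        assert total == pytest.approx(parts, abs=1e-9)

    def test_zero_weights_reduce_to_dice(self):
        probs, targets = _random_case(seed=6)
        params = HybridLossParams(focal_weight=0.0, ce_weight=0.0)
        assert hybrid_loss(probs, targets, params).item() == pytest.approx(
            dice_loss(probs, targets).item(), abs=1e-12)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            HybridLossParams(epsilon=0.0)


class TestArchitecture:
    def test_unet_feature_ladder(self):
        cfg = FusionConfig.preset("tiny", strategy="none")
        model = MAEFUnet(cfg, seed=0)
        feats = model.unet_features(RNG.random((1, 64, 64)))
        shapes = [f.shape for f in feats]
        assert shapes == [(1, 16, 64, 64), (1, 32, 32, 32), (1, 64, 16, 16),
                          (1, 128, 8, 8)]

    @pytest.mark.parametrize("preset,enc", [("tiny", (64, 4)),
                                            ("vitbase", (768, 12))])
    def test_fusion_parameter_ordering(self, preset, enc):
        dim, layers = enc
        counts = {}
        for strat in ("add", "concat", "attention"):
            cfg = FusionConfig.preset(preset, strategy=strat)
            counts[strat] = MAEFUnet(cfg, dim, layers, seed=0).n_parameters()
        assert counts["add"] < counts["concat"] < counts["attention"]

    @pytest.mark.parametrize("preset,enc,widths",
                             [("tiny", (64, 4), (8, 16, 24)),
                              ("vitbase", (768, 12), (32, 64, 96))])
    def test_width_parameter_ordering(self, preset, enc, widths):
        dim, layers = enc
        counts = [
            MAEFUnet(FusionConfig.preset(preset, base_channels=w),
                     dim, layers, seed=0).n_parameters()
            for w in widths
        ]
        assert counts[0] < counts[1] < counts[2]

    def test_strategy_swap_changes_only_fusion_blocks(self):
        shapes = {}
        values = {}
        for strat in ("add", "concat", "attention"):
            m = MAEFUnet(FusionConfig.preset("tiny", strategy=strat),
                         64, 4, seed=0)
            named = m.named_parameters()
            shapes[strat] = {n: p.shape for n, p in named
                             if "fusion_blocks" not in n}
            values[strat] = {n: p.data.copy() for n, p in named
                             if "fusion_blocks" not in n}
        assert shapes["add"] == shapes["concat"] == shapes["attention"]
        for n in values["add"]:
            assert np.array_equal(values["add"][n], values["attention"][n])

    def test_tap_layer_out_of_range(self):
        cfg = FusionConfig.preset("tiny", tap_layers=(1, 2, 3, 9))
        with pytest.raises(ValueError):
            MAEFUnet(cfg, 64, 4, seed=0)

    def test_invalid_fusion_configs(self):
        with pytest.raises(ValueError):
            FusionConfig(strategy="mystery")
        with pytest.raises(ValueError):
            FusionConfig(strategy="concat", tap_layers=(1, 2), depth=4)


class TestFusionBlock:
    def test_add_with_zero_projection_is_identity(self):
        rng = np.random.default_rng(0)
        blk = FusionBlock("add", 8, 16, rng)
        blk.proj.weight.data[:] = 0
        blk.proj.bias.data[:] = 0
        f = Tensor(RNG.random((2, 8, 16, 16)))
        tokens = RNG.random((2, 16, 16))
        out = blk(f, tokens)
        assert np.allclose(out.data, f.data)

    def test_attention_output_shape_matches_query(self):
        blk = FusionBlock("attention", 8, 16, np.random.default_rng(0))
        f = Tensor(RNG.random((2, 8, 16, 16)))
        out = blk(f, RNG.random((2, 16, 16)))
        assert out.shape == f.shape

    def test_projection_contracts(self):
        blk = FusionBlock("concat", 6, 16, np.random.default_rng(0))
        tokens = RNG.random((1, 16, 16))  # 4x4 grid
        native = blk.project(tokens, 4, 4)
        assert native.shape == (1, 6, 4, 4)
        up = blk.project(tokens, 16, 16)
        assert up.shape == (1, 6, 16, 16)
        # constant token field projects to a spatially constant map
        const = np.tile(RNG.random((1, 1, 16)), (1, 16, 1))
        out = blk.project(const, 12, 12).data
        assert np.allclose(out, out[:, :, :1, :1], atol=1e-10)


class TestMAEDirect:
    def test_output_spatial_dims_and_determinism(self):
        m = MAEDirect(64, 8, 64, n_classes=2, seed=0)
        tokens = RNG.random((2, 64, 64))
        a = m(tokens)
        b = m(tokens)
        assert a.shape == (2, 2, 64, 64)
        assert np.array_equal(a.data, b.data)

    def test_fewer_parameters_than_funet(self):
        direct = MAEDirect(64, 8, 64, n_classes=2, seed=0)
        funet = MAEFUnet(FusionConfig.preset("tiny"), 64, 4, seed=0)
        assert direct.n_parameters() < funet.n_parameters()


class TestTrainingContracts:
    def test_softmax_channel_sums(self):
        m = MAEFUnet(FusionConfig.preset("tiny", strategy="none"), seed=0)
        with nn.no_grad():
            probs = m(RNG.random((2, 64, 64))).softmax(axis=1)
        assert np.allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)

    def test_plain_unet_trains_through_same_path(self, downstream_cohort):
        from maefew.fewshot import FewShotSpec, build_segmentation_split

        vols = downstream_cohort["T1"][:2]
        spec = FewShotSpec(task="skull_strip", stride_k=10, axes=("axial",),
                           image_size=64, seed=0)
        split = build_segmentation_split(vols, spec)
        ck = train_segmenter(split.train[:6], None,
                             FusionConfig.preset("tiny", strategy="none"),
                             seed=0, epochs=2, batch_size=4)
        assert len(ck.loss_curve) == 2
        assert ck.loss_curve[1] < ck.loss_curve[0]

    def test_label_out_of_range_rejected(self, downstream_cohort):
        from maefew.fewshot import FewShotSpec, build_segmentation_split

        vols = downstream_cohort["T1"][:2]
        spec = FewShotSpec(task="anatomy", n_volumes=1, axes=("axial",),
                           image_size=64, seed=0)
        split = build_segmentation_split(vols, spec)
        mid = len(split.train) // 2  # central slices contain all tissue classes
        with pytest.raises(ValueError):
            train_segmenter(split.train[mid : mid + 4], None,
                            FusionConfig.preset("tiny", strategy="none",
                                                n_classes=2),
                            target="labels", seed=0, epochs=1)
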