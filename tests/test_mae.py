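"""MAE core: patchification, masking, coverage weighting, pretraining."""

import numpy as np
import pytest

from maefew.mae import (
    MAEModel,
    MaskPlan,
    SampleLoss,
    ViTConfig,
    coverage_weight,
    patchify,
    per_sample_masked_mse,
    pretrain,
    random_mask,
    unpatchify,
    weighted_batch_loss,
    load_checkpoint,
    save_checkpoint,
)

RNG = np.random.default_rng(0)


class TestPatchify:
    def test_vitbase_patch_count_and_size(self):
        x = RNG.random((224, 224))
        p = patchify(x, 16)
        assert p.shape == (196, 256)

    def test_roundtrip_bit_exact(self):
        x = RNG.random((3, 64, 64))
        assert np.array_equal(unpatchify(patchify(x, 8), 8), x)

    def test_constant_image_gives_identical_patches(self):
        p = patchify(np.full((32, 32), 0.5), 8)
        assert np.all(p == p[0])

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ValueError):
            patchify(np.zeros((30, 30)), 16)


class TestRandomMask:
    def test_counts_at_three_quarters(self):
        plan = random_mask(196, 0.75, seed=0)
        assert len(plan.masked_indices) == 147
        assert len(plan.kept_indices) == 49

    def test_deterministic_and_partition(self):
        a = random_mask(64, 0.75, seed=5)
        b = random_mask(64, 0.75, seed=5)
        assert np.array_equal(a.masked_indices, b.masked_indices)
        union = set(a.masked_indices) | set(a.kept_indices)
        assert union == set(range(64))
        assert not set(a.masked_indices) & set(a.kept_indices)

    def test_invalid_ratio(self):
        for ratio in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                random_mask(64, ratio, seed=0)


class TestCoverageWeight:
    def test_endpoints(self):
        assert coverage_weight(1.0) == pytest.approx(1.0)
        assert coverage_weight(0.0) == pytest.approx(0.1)

    def test_strictly_increasing(self):
        grid = np.linspace(0, 1, 101)
        w = coverage_weight(grid)
        assert np.all(np.diff(w) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            coverage_weight(1.5)


class TestMaskedMse:
    def test_perfect_reconstruction(self):
        t = RNG.random((16, 4))
        plan = random_mask(16, 0.5, seed=1)
        assert per_sample_masked_mse(t, t, plan) == 0.0

    def test_kept_patches_do_not_contribute(self):
        target = RNG.random((16, 4))
        recon = target.copy()
        plan = random_mask(16, 0.5, seed=1)
        recon[plan.kept_indices] += 100.0
        assert per_sample_masked_mse(recon, target, plan) == 0.0

    def test_hand_mean(self):
        target = np.zeros((2, 1))
        recon = np.array([[0.2], [0.4]])  # squared errors 0.04, 0.16
        plan = MaskPlan(masked_indices=np.array([0, 1]),
                        kept_indices=np.array([], dtype=int), seed=0)
        assert per_sample_masked_mse(recon, target, plan) == pytest.approx(0.10)

    def test_empty_masked_set_rejected(self):
        plan = MaskPlan(masked_indices=np.array([], dtype=int),
                        kept_indices=np.arange(4), seed=0)
        with pytest.raises(ValueError):
            per_sample_masked_mse(np.zeros((4, 2)), np.zeros((4, 2)), plan)


class TestWeightedBatchLoss:
    def test_uniform_weights_reduce_to_mean(self):
        ls = [SampleLoss(l, 0.5, 1.0) for l in (0.1, 0.3, 0.8)]
        assert weighted_batch_loss(ls) == pytest.approx(np.mean([0.1, 0.3, 0.8]))

    def test_hand_value(self):
        ls = [SampleLoss(3.0, 1.0, 2.0), SampleLoss(5.0, 0.0, 0.1)]
        assert weighted_batch_loss(ls) == pytest.approx(3.25)

    def test_linearity_in_weights(self):
        base = [SampleLoss(0.2, 0.3, 0.5), SampleLoss(0.7, 0.9, 0.8)]
        scaled = [SampleLoss(s.l_tilde, s.alpha, 3.0 * s.weight) for s in base]
        assert weighted_batch_loss(scaled) == pytest.approx(
            3.0 * weighted_batch_loss(base))

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            weighted_batch_loss([])


def test_config_invariants():
    with pytest.raises(ValueError):
        ViTConfig(image_size=100, patch_size=16)
    with pytest.raises(ValueError):
        ViTConfig(mask_ratio=1.2)
    tiny = ViTConfig.preset("tiny")
    assert tiny.image_size % tiny.patch_size == 0
    assert tiny.n_patches == 64


def test_encode_token_sequence_contract(tiny_config):
    model = MAEModel(tiny_config, seed=1)
    seq = model.encode(RNG.random((64, 64)))
    assert seq.tokens.shape == (tiny_config.n_patches + 1,
                                tiny_config.encoder_dim)
    assert len(seq.per_layer_states) == tiny_config.encoder_layers
    assert seq.patch_grid == (8, 8)


def test_encoder_batch_order_invariance(tiny_config):
    model = MAEModel(tiny_config, seed=0)
    images = RNG.random((4, 64, 64))
    plans = [random_mask(64, 0.75, seed=i) for i in range(4)]
    l1, _ = model.forward_pretrain(images, plans)
    perm = [2, 0, 3, 1]
    l2, _ = model.forward_pretrain(images[perm], [plans[i] for i in perm])
    assert np.allclose(l2.data, l1.data[perm], atol=1e-10)


def test_pretrain_loss_decreases(tiny_ckpt):
    assert tiny_ckpt.loss_curve[-1] < tiny_ckpt.loss_curve[0]


def test_resume_reproduces_longer_run(pretrain_samples, tiny_config, tmp_path):
    subset = pretrain_samples[:24]
    full = pretrain(subset, tiny_config, epochs=3, batch_size=8, seed=9)
    short = pretrain(subset, tiny_config, epochs=2, batch_size=8, seed=9)
    save_checkpoint(short, tmp_path / "ck")
    resumed = pretrain(subset, tiny_config, epochs=1, batch_size=8, seed=9,
                       resume=load_checkpoint(tmp_path / "ck"))
    assert resumed.loss_curve[:2] == full.loss_curve[:2]
    assert resumed.loss_curve[2] == pytest.approx(full.loss_curve[2], abs=1e-6)


def test_checkpoint_roundtrip(pretrain_samples, tiny_config, tmp_path):
    ck = pretrain(pretrain_samples[:16], tiny_config, epochs=1, batch_size=8,
                  seed=2)
    save_checkpoint(ck, tmp_path / "m")
    back = load_checkpoint(tmp_path / "m")
    assert back.model.weight_hash() == ck.model.weight_hash()
    assert back.loss_curve == ck.loss_curve


def test_size_mismatch_rejected(pretrain_samples):
    with pytest.raises(ValueError):
        pretrain(pretrain_samples[:8], ViTConfig.preset("vitbase"), epochs=1)
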