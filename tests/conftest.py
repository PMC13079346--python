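"""Shared fixtures: phantom cohorts and a pretrained tiny encoder.

Expensive artifacts (the pretrained encoder, trained probe and segmenter)
are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import time

import numpy as np
import pytest

from maefew.fewshot import (
    FewShotSpec,
    build_classification_split,
    build_segmentation_split,
    remap_volume_to_slices,
)
from maefew.funet import FusionConfig, encode_for_fusion, train_segmenter
from maefew.mae import ViTConfig, pretrain
from maefew.phantom import PhantomSpec, generate_cohort, generate_phantom
from maefew.probe import extract_cls, predict, train_probe

PRETRAIN_SEED = 101
DOWNSTREAM_SEED = 3


@pytest.fixture(scope="session")
def tiny_config() -> ViTConfig:
    return ViTConfig.preset("tiny")


@pytest.fixture(scope="session")
def phantom_volumes():
    """One subject, all four sequences, default spec."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def pretrain_samples():
    """320 slices from 8 pretraining subjects, all axes, empties included."""
    cohort = generate_cohort(PhantomSpec(seed=PRETRAIN_SEED), 8)
    rng = np.random.default_rng(0)
    samples = []
    for seq in sorted(cohort):
        for vol in cohort[seq]:
            sl = remap_volume_to_slices(vol, min_foreground=0, image_size=64)
            pick = rng.choice(len(sl), 10, replace=False)
            samples.extend(sl[i] for i in sorted(pick))
    return samples


@pytest.fixture(scope="session")
def tiny_ckpt(pretrain_samples, tiny_config):
    """Coverage-weighted MAE pretraining at desk scale (timed)."""
    t0 = time.time()
    ckpt = pretrain(pretrain_samples, tiny_config, epochs=25, batch_size=8,
                    seed=0)
    ckpt.wall_time_s = time.time() - t0
    return ckpt


@pytest.fixture(scope="session")
def downstream_cohort():
    """Six held-out subjects (disjoint seeds from the pretraining cohort)."""
    return generate_cohort(PhantomSpec(seed=DOWNSTREAM_SEED), 6)


@pytest.fixture(scope="session")
def probe_results(tiny_ckpt, downstream_cohort):
    """Few-shot sequence classification: split, trained head, predictions."""
    t0 = time.time()
    split = build_classification_split(
        downstream_cohort, n_slices_per_sequence=10, seed=1, image_size=64,
        min_foreground=410, max_test_slices_per_sequence=30,
    )
    enc_hash_before = tiny_ckpt.model.encoder_hash()
    head, log = train_probe(split.train, tiny_ckpt.model,
                            len(split.class_names), seed=0,
                            class_names=split.class_names)
    enc_hash_after = tiny_ckpt.model.encoder_hash()
    feats = extract_cls(tiny_ckpt.model,
                        np.stack([s.image for s in split.test]))
    pred, probs = predict(head, feats)
    true = np.array([s.sequence_label for s in split.test])
    return {
        "split": split,
        "head": head,
        "log": log,
        "pred": pred,
        "probs": probs,
        "true": true,
        "accuracy": float(np.mean(pred == true)),
        "encoder_hash_before": enc_hash_before,
        "encoder_hash_after": enc_hash_after,
        "wall_time_s": time.time() - t0,
    }


@pytest.fixture(scope="session")
def skullstrip_results(tiny_ckpt, downstream_cohort):
    """Few-shot skull stripping with the tiny FUnet (stride-7 sampling)."""
    t0 = time.time()
    volumes = [v for seq in sorted(downstream_cohort)
               for v in downstream_cohort[seq]]
    spec = FewShotSpec(task="skull_strip", stride_k=7, axes=("axial",),
                       image_size=64, seed=0)
    split = build_segmentation_split(volumes, spec)
    rng = np.random.default_rng(5)
    test = [split.test[i]
            for i in sorted(rng.choice(len(split.test), 48, replace=False))]
    fusion = FusionConfig.preset("tiny")
    enc_hash_before = tiny_ckpt.model.encoder_hash()
    ckpt = train_segmenter(split.train, tiny_ckpt.model, fusion,
                           target="brain_mask", seed=0, epochs=16,
                           batch_size=8)
    enc_hash_after = tiny_ckpt.model.encoder_hash()
    images = np.stack([s.image for s in test])
    cache = encode_for_fusion(tiny_ckpt.model, images, fusion.tap_layers)
    from maefew.funet import predict_segmentation

    pred = predict_segmentation(ckpt.model, images, cache)
    truth = np.stack([s.brain_mask for s in test]).astype(np.int64)
    from maefew.metrics import dice_iou

    dices = [dice_iou(pred[i] > 0, truth[i] > 0)[0] for i in range(len(test))]
    return {
        "split": split,
        "ckpt": ckpt,
        "pred": pred,
        "truth": truth,
        "mean_dice": float(np.mean(dices)),
        "n_train": len(split.train),
        "encoder_hash_before": enc_hash_before,
        "encoder_hash_after": enc_hash_after,
        "wall_time_s": time.time() - t0,
    }
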