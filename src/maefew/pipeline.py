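"""End-to-end desk-scale experiment pipelines and sweep drivers.

``run_experiment`` executes phantom generation, coverage-weighted MAE
pretraining, and the selected downstream task (linear-probe classification,
skull stripping, or multi-class anatomy segmentation), writing checkpoints,
metrics and logs to a run directory.  Pretraining uses a dedicated phantom
cohort whose subjects are disjoint from the downstream cohort, so no scan
seen at fine-tuning time ever enters pretraining.

``sweep`` repeats an experiment along one axis (stride, training-set size,
backbone width or fusion strategy) and summarizes score stability.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import fewshot as fs
from . import metrics as M
from .config import ExperimentConfig
from .funet import (
    FusionConfig,
    encode_for_fusion,
    predict_segmentation,
    train_segmenter,
)
from .mae import pretrain, save_checkpoint
from .phantom import PhantomSpec, generate_cohort
from .preprocess import SliceSample
from .probe import extract_cls, predict, train_probe

__all__ = ["run_experiment", "sweep", "build_pretrain_set"]


def build_pretrain_set(config: ExperimentConfig, n_subjects: int = 8,
                       slices_per_volume: int = 10) -> list[SliceSample]:
    """Pretraining slices from a cohort disjoint from the downstream one.

    Slices are drawn from all three axes with no foreground filtering, so
    empty and partial-coverage slices are present and the coverage-weighted
    loss is exercised.
    """
    seed = config.stage_seed("phantom-pretrain")
    spec = PhantomSpec(grid_size=config.grid_size, noise_sd=config.noise_sd,
                       seed=seed)
    cohort = generate_cohort(spec, n_subjects)
    rng = np.random.default_rng(config.stage_seed("pretrain-sampling"))
    samples: list[SliceSample] = []
    for seq in sorted(cohort):
        for vol in cohort[seq]:
            slices = fs.remap_volume_to_slices(
                vol, axes=("sagittal", "coronal", "axial"), min_foreground=0,
                image_size=config.vit.image_size,
            )
            take = min(slices_per_volume, len(slices))
            pick = rng.choice(len(slices), size=take, replace=False)
            samples.extend(slices[i] for i in sorted(pick))
    return samples


def _downstream_cohort(config: ExperimentConfig):
    seed = config.stage_seed("phantom-downstream")
    spec = PhantomSpec(grid_size=config.grid_size, noise_sd=config.noise_sd,
                       seed=seed)
    return generate_cohort(spec, config.n_subjects)


def _subsample(samples: list, n: int, seed: int) -> list:
    if n is None or len(samples) <= n:
        return samples
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(samples), size=n, replace=False)
    return [samples[i] for i in sorted(pick)]


def run_experiment(config: ExperimentConfig,
                   max_eval_slices: Optional[int] = 64) -> dict:
    """Run the configured pipeline; returns the metrics dict.

    The run directory receives the resolved config (with content hash), the
    pretraining checkpoint, a metrics JSON and a stage-state file that makes
    reruns resumable at the pretraining boundary.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    (out / "config.hash").write_text(config.content_hash())
    state_path = out / "state.json"
    state = json.loads(state_path.read_text()) if state_path.exists() else {}
    t0 = time.time()

    # ---- stage: pretrain (resumable) ------------------------------------
    ckpt_path = out / "mae_checkpoint"
    if state.get("pretrain") == "done" and ckpt_path.with_suffix(".npz").exists():
        from .mae import load_checkpoint

        mae_ckpt = load_checkpoint(ckpt_path)
    else:
        pre_set = build_pretrain_set(config)
        mae_ckpt = pretrain(
            pre_set,
            config.vit,
            epochs=config.pretrain_epochs,
            batch_size=config.optimizer.batch_size,
            lr=config.optimizer.lr,
            weight_decay=config.optimizer.weight_decay,
            seed=config.stage_seed("pretrain"),
        )
        save_checkpoint(mae_ckpt, ckpt_path)
        state["pretrain"] = "done"
        state_path.write_text(json.dumps(state))

    cohort = _downstream_cohort(config)
    results: dict = {
        "task": config.task,
        "pretrain_loss_first": mae_ckpt.loss_curve[0],
        "pretrain_loss_last": mae_ckpt.loss_curve[-1],
    }

    # ---- stage: downstream task -----------------------------------------
    eval_seed = config.stage_seed("eval-subsample")
    if config.task == "classification":
        # sequence contrast is a property of brain tissue: keep slices with
        # at least 10% brain coverage in the classification protocol
        min_fg = max(1, int(0.10 * config.vit.image_size**2))
        split = fs.build_classification_split(
            cohort,
            n_slices_per_sequence=config.fewshot.n_slices_per_sequence,
            seed=config.stage_seed("split"),
            image_size=config.vit.image_size,
            min_foreground=min_fg,
            max_test_slices_per_sequence=max_eval_slices,
        )
        n_classes = len(split.class_names)
        head, _ = train_probe(
            split.train, mae_ckpt.model, n_classes,
            seed=config.stage_seed("probe"), epochs=config.probe_epochs,
            lr=config.optimizer.lr, class_names=split.class_names,
        )
        feats = extract_cls(mae_ckpt.model,
                            np.stack([s.image for s in split.test]))
        pred_labels, _ = predict(head, feats)
        true_labels = np.array([s.sequence_label for s in split.test])
        counts = M.confusion(true_labels, pred_labels, n_classes)
        report = M.classification_report(counts)
        results.update(report.to_dict())
        results["n_train"] = len(split.train)
        results["n_test"] = len(split.test)
    else:
        axes = ("axial",) if config.task == "skull_strip" else config.fewshot.axes
        spec = dataclasses.replace(config.fewshot, task=config.task, axes=axes,
                                   image_size=config.vit.image_size)
        if config.task == "skull_strip":
            volumes = [v for seq in sorted(cohort) for v in cohort[seq]]
            target, n_classes = "brain_mask", 2
        else:
            volumes = cohort[sorted(cohort)[0]]  # anatomy uses one sequence
            target, n_classes = "labels", int(volumes[0].labels.max()) + 1
        split = fs.build_segmentation_split(volumes, spec)
        test = _subsample(split.test, max_eval_slices, eval_seed)
        fusion = dataclasses.replace(config.fusion, n_classes=n_classes)
        seg = train_segmenter(
            split.train, mae_ckpt.model, fusion, target=target,
            seed=config.stage_seed("segment"), epochs=config.train_epochs,
            batch_size=config.optimizer.batch_size, lr=config.optimizer.lr,
        )
        images = np.stack([s.image for s in test])
        cache = (
            encode_for_fusion(mae_ckpt.model, images, fusion.tap_layers)
            if fusion.strategy != "none" else None
        )
        pred_maps = predict_segmentation(seg.model, images, cache)
        truth = np.stack(
            [s.brain_mask if target == "brain_mask" else s.labels for s in test]
        ).astype(np.int64)
        report = M.multiclass_dice_iou(pred_maps, truth, n_classes)
        results.update(report.to_dict())
        results["n_train"] = len(split.train)
        results["n_test"] = len(test)
        results["trainable_params"] = seg.model.n_parameters()

    results["wall_time_s"] = time.time() - t0
    (out / "metrics.json").write_text(json.dumps(results, indent=2))
    return results


_SWEEP_DEFAULTS = {
    "stride": (4, 5, 6, 7, 8, 9, 10),
    "n_slices": (10, 20, 30, 50, 100),
    "n_volumes": (10, 20, 30, 50, 100),
    "width": (32, 64, 96),
    "fusion": ("add", "concat", "attention"),
}


def sweep(config: ExperimentConfig, axis: str,
          values: Optional[Sequence] = None) -> pd.DataFrame:
    """One run per axis value plus mean/std (population) summary rows."""
    if axis not in _SWEEP_DEFAULTS:
        raise ValueError(f"unknown sweep axis {axis!r}")
    values = list(values if values is not None else _SWEEP_DEFAULTS[axis])
    if not values:
        raise ValueError("empty sweep axis")
    rows = []
    base_out = Path(config.output_dir)
    for i, v in enumerate(values):
        cfg = dataclasses.replace(
            config,
            output_dir=str(base_out / f"{axis}_{v}"),
            seed=config.stage_seed(f"sweep-{axis}", i),
        )
        if axis == "stride":
            cfg.task = "skull_strip"
            cfg.fewshot = dataclasses.replace(cfg.fewshot, stride_k=int(v))
        elif axis == "n_slices":
            cfg.task = "classification"
            cfg.fewshot = dataclasses.replace(cfg.fewshot,
                                              n_slices_per_sequence=int(v))
        elif axis == "n_volumes":
            cfg.task = "anatomy"
            cfg.fewshot = dataclasses.replace(cfg.fewshot, n_volumes=int(v))
        elif axis == "width":
            cfg.fusion = dataclasses.replace(cfg.fusion, base_channels=int(v))
        elif axis == "fusion":
            cfg.fusion = dataclasses.replace(cfg.fusion, strategy=str(v))
        res = run_experiment(cfg)
        score = res.get("mean_iou", res.get("accuracy"))
        row = {axis: v, "score": score}
        if "mean_dice" in res:
            row["dice"] = res["mean_dice"]
        if "trainable_params" in res:
            row["trainable_params"] = res["trainable_params"]
        rows.append(row)
    df = pd.DataFrame(rows)
    summ = M.stability(df["score"].tolist())
    extra = pd.DataFrame(
        [{axis: "mean", "score": summ.mean}, {axis: "std", "score": summ.std}]
    )
    out = pd.concat([df, extra], ignore_index=True)
    out.to_csv(base_out / f"sweep_{axis}.csv", index=False)
    return out
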