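"""Experiment configuration, presets, and seed derivation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from .fewshot import FewShotSpec
from .funet import FusionConfig
from .mae import ViTConfig

__all__ = ["ExperimentConfig", "OptimizerConfig", "derive_seed"]


def derive_seed(master_seed: int, stage: str, counter: int = 0) -> int:
    """Per-stage seed derived from the master seed via a counter-based hash.

    Stages get independent, reproducible streams; results stay below 2**31.
    """
    h = hashlib.sha256(f"{master_seed}:{stage}:{counter}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass(frozen=True)
class OptimizerConfig:
    lr: float = 1e-4
    batch_size: int = 48
    weight_decay: float = 0.01


@dataclass
class ExperimentConfig:
    """Resolved configuration of one end-to-end run."""

    preset: Literal["tiny", "vitbase"] = "tiny"
    task: Literal["classification", "skull_strip", "anatomy"] = "classification"
    fewshot: FewShotSpec = field(default_factory=FewShotSpec)
    vit: ViTConfig = field(default_factory=lambda: ViTConfig.preset("tiny"))
    fusion: FusionConfig = field(default_factory=lambda: FusionConfig.preset("tiny"))
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    pretrain_epochs: int = 25
    train_epochs: int = 25
    probe_epochs: int = 2000
    n_subjects: int = 6
    grid_size: int = 64
    noise_sd: float = 0.02
    seed: int = 0
    output_dir: str = "runs/exp"

    @classmethod
    def preset_config(cls, name: str, **over) -> "ExperimentConfig":
        if name == "tiny":
            cfg = cls(
                preset="tiny",
                vit=ViTConfig.preset("tiny"),
                fusion=FusionConfig.preset("tiny"),
                fewshot=FewShotSpec(image_size=64),
                optimizer=OptimizerConfig(batch_size=8),
            )
        elif name == "vitbase":
            cfg = cls(
                preset="vitbase",
                vit=ViTConfig.preset("vitbase"),
                fusion=FusionConfig.preset("vitbase"),
                fewshot=FewShotSpec(image_size=224),
                grid_size=224,
                pretrain_epochs=100,
                train_epochs=100,
            )
        else:
            raise ValueError(f"unknown preset {name!r}")
        for k, v in over.items():
            setattr(cfg, k, v)
        return cfg

    # ------------------------------------------------------------- ser/de
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["fewshot"] = FewShotSpec(**{**d["fewshot"],
                                      "axes": tuple(d["fewshot"]["axes"])})
        d["vit"] = ViTConfig(**d["vit"])
        d["fusion"] = FusionConfig(**{**d["fusion"],
                                      "tap_layers": tuple(d["fusion"]["tap_layers"])})
        d["optimizer"] = OptimizerConfig(**d["optimizer"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str, counter: int = 0) -> int:
        return derive_seed(self.seed, stage, counter)
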