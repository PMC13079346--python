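"""Masked-autoencoder pretraining with brain-coverage-weighted loss.

A ViT encoder/decoder pair is trained to reconstruct randomly masked image
patches.  Because aggregated MRI cohorts contain many slices with little or
no brain tissue (apex/base slices, cropped fields of view), each sample's
masked-patch MSE is weighted by a monotone increasing function of its
brain-coverage fraction alpha before batch averaging:

    L = (1/N) * sum_i w_i * l_i,   w_i = f(alpha_i)

so background-dominated slices pull less on the encoder.  The batch gradient
is therefore the same weighted average of per-sample gradients.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .nn import Tensor
from .preprocess import SliceSample

__all__ = [
    "ViTConfig",
    "MaskPlan",
    "SampleLoss",
    "TokenSequence",
    "MAEModel",
    "MAECheckpoint",
    "patchify",
    "unpatchify",
    "random_mask",
    "coverage_weight",
    "per_sample_masked_mse",
    "weighted_batch_loss",
    "pretrain",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ViTConfig:
    """Transformer encoder/decoder geometry.

    ``vitbase`` mirrors the ViT-Base configuration (224 input, 16x16
    patches, 12 encoder layers, width 768); ``tiny`` is a desk-scale preset
    (64 input, 8x8 patches, 4 layers, width 64) satisfying the same
    invariants.
    """

    image_size: int = 224
    patch_size: int = 16
    encoder_layers: int = 12
    encoder_dim: int = 768
    encoder_heads: int = 12
    decoder_layers: int = 8
    decoder_dim: int = 512
    decoder_heads: int = 8
    in_channels: int = 1
    mask_ratio: float = 0.75

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise ValueError("image_size must be divisible by patch_size")
        if not 0.0 < self.mask_ratio < 1.0:
            raise ValueError("mask_ratio must lie in (0, 1)")
        if self.encoder_dim % self.encoder_heads or self.decoder_dim % self.decoder_heads:
            raise ValueError("width must divide by number of heads")
        if self.in_channels != 1:
            raise ValueError("grayscale input only (in_channels=1)")

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.grid**2

    @classmethod
    def preset(cls, name: str) -> "ViTConfig":
        if name == "tiny":
            return cls(image_size=64, patch_size=8, encoder_layers=4,
                       encoder_dim=64, encoder_heads=4, decoder_layers=2,
                       decoder_dim=64, decoder_heads=4)
        if name == "vitbase":
            return cls()
        raise ValueError(f"unknown preset {name!r}")


@dataclass
class MaskPlan:
    """Random patch-masking pattern for one pretraining sample."""

    masked_indices: np.ndarray
    kept_indices: np.ndarray
    seed: int

    def __post_init__(self):
        m = set(self.masked_indices.tolist())
        k = set(self.kept_indices.tolist())
        if m & k:
            raise ValueError("masked and kept indices must be disjoint")


@dataclass
class SampleLoss:
    """Per-sample pretraining loss record."""

    l_tilde: float
    alpha: float
    weight: float

    def __post_init__(self):
        if self.l_tilde < 0 or not 0 <= self.alpha <= 1 or self.weight <= 0:
            raise ValueError("invalid SampleLoss fields")


@dataclass
class TokenSequence:
    """Encoder states of one forward pass (CLS at position 0)."""

    tokens: np.ndarray  # (n_patches+1, d), after final layer norm
    per_layer_states: list[np.ndarray]  # E arrays of the same shape
    patch_grid: tuple[int, int]


def patchify(image: np.ndarray, patch_size: int) -> np.ndarray:
    """(..., H, W) -> (..., n_patches, patch_size**2), row-major patch order."""
    image = np.asarray(image)
    h, w = image.shape[-2:]
    if h % patch_size or w % patch_size:
        raise ValueError("image dims must be divisible by patch_size")
    gh, gw = h // patch_size, w // patch_size
    lead = image.shape[:-2]
    x = image.reshape(*lead, gh, patch_size, gw, patch_size)
    x = np.moveaxis(x, -3, -2)  # (..., gh, gw, p, p)
    return x.reshape(*lead, gh * gw, patch_size * patch_size)


def unpatchify(patches: np.ndarray, patch_size: int) -> np.ndarray:
    """Inverse of :func:`patchify` (bit-exact round trip)."""
    patches = np.asarray(patches)
    n = patches.shape[-2]
    g = int(round(np.sqrt(n)))
    if g * g != n:
        raise ValueError("patch count must be a perfect square")
    lead = patches.shape[:-2]
    x = patches.reshape(*lead, g, g, patch_size, patch_size)
    x = np.moveaxis(x, -2, -3)
    return x.reshape(*lead, g * patch_size, g * patch_size)


def random_mask(n_patches: int, mask_ratio: float, seed: int) -> MaskPlan:
    """Uniform masking without replacement; deterministic per seed."""
    if not 0.0 < mask_ratio < 1.0:
        raise ValueError("mask_ratio must lie in (0, 1)")
    n_masked = int(round(mask_ratio * n_patches))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_patches)
    return MaskPlan(
        masked_indices=np.sort(perm[:n_masked]),
        kept_indices=np.sort(perm[n_masked:]),
        seed=seed,
    )


def coverage_weight(alpha, w_min: float = 0.1):
    """Monotone increasing coverage-to-weight map f(alpha) = w_min + (1-w_min)*alpha."""
    a = np.asarray(alpha, dtype=np.float64)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("alpha must lie in [0, 1]")
    w = w_min + (1.0 - w_min) * a
    return float(w) if np.isscalar(alpha) or a.ndim == 0 else w


def per_sample_masked_mse(reconstruction: np.ndarray, target: np.ndarray,
                          plan: MaskPlan) -> float:
    """Mean squared error over the masked patches only."""
    reconstruction = np.asarray(reconstruction, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if reconstruction.shape != target.shape:
        raise ValueError("shape mismatch")
    if len(plan.masked_indices) == 0:
        raise ValueError("empty masked set")
    diff = reconstruction[plan.masked_indices] - target[plan.masked_indices]
    return float(np.mean(diff**2))


def weighted_batch_loss(samples: Sequence[SampleLoss]) -> float:
    """Batch loss L = (1/N) * sum_i w_i * l_i (no renormalization by sum w)."""
    if len(samples) == 0:
        raise ValueError("empty batch")
    return float(np.mean([s.weight * s.l_tilde for s in samples]))


# ------------------------------------------------------------------ model


def _sincos_1d(dim: int, pos: np.ndarray) -> np.ndarray:
    omega = 1.0 / 10000 ** (np.arange(dim // 2) / (dim / 2.0))
    out = pos[:, None] * omega[None, :]
    return np.concatenate([np.sin(out), np.cos(out)], axis=1)


def sincos_pos_embed(dim: int, grid: int, cls_token: bool = True) -> np.ndarray:
    """Fixed 2D sin-cos positional embeddings on a grid, optional CLS slot."""
    if dim % 4:
        raise ValueError("embedding dim must be divisible by 4")
    coords = np.arange(grid, dtype=np.float64)
    gy, gx = np.meshgrid(coords, coords, indexing="ij")
    emb = np.concatenate(
        [_sincos_1d(dim // 2, gy.ravel()), _sincos_1d(dim // 2, gx.ravel())], axis=1
    )
    if cls_token:
        emb = np.concatenate([np.zeros((1, dim)), emb], axis=0)
    return emb


class MAEModel(nn.Module):
    """ViT encoder + lightweight decoder for masked reconstruction."""

    def __init__(self, config: ViTConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        p2 = c.patch_size**2 * c.in_channels
        self.patch_embed = nn.Linear(p2, c.encoder_dim, rng)
        self.cls_token = nn.Parameter(rng.normal(0, 0.02, size=(1, 1, c.encoder_dim)))
        self.enc_pos = sincos_pos_embed(c.encoder_dim, c.grid)  # constant
        self.blocks = [
            nn.TransformerBlock(c.encoder_dim, c.encoder_heads, rng)
            for _ in range(c.encoder_layers)
        ]
        self.norm = nn.LayerNorm(c.encoder_dim)
        # decoder
        self.decoder_embed = nn.Linear(c.encoder_dim, c.decoder_dim, rng)
        self.mask_token = nn.Parameter(rng.normal(0, 0.02, size=(1, 1, c.decoder_dim)))
        self.dec_pos = sincos_pos_embed(c.decoder_dim, c.grid)
        self.dec_blocks = [
            nn.TransformerBlock(c.decoder_dim, c.decoder_heads, rng)
            for _ in range(c.decoder_layers)
        ]
        self.dec_norm = nn.LayerNorm(c.decoder_dim)
        self.dec_head = nn.Linear(c.decoder_dim, p2, rng)

    # -------------------------------------------------------------- encoder
    def _embed(self, images: np.ndarray) -> Tensor:
        patches = patchify(images, self.config.patch_size)
        tokens = self.patch_embed(Tensor(patches))
        return tokens + Tensor(self.enc_pos[None, 1:, :])

    def forward_encoder(self, images: np.ndarray,
                        kept: np.ndarray | None = None
                        ) -> tuple[Tensor, list[Tensor]]:
        """Run the encoder; ``kept`` (N, n_keep) restricts to visible patches.

        Returns the final-normed token sequence (CLS at position 0) and the
        list of per-block states (pre final norm).
        """
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        n = images.shape[0]
        tokens = self._embed(images)
        if kept is not None:
            tokens = tokens[np.arange(n)[:, None], kept]
        cls = self.cls_token + Tensor(self.enc_pos[None, :1, :])
        cls = cls * Tensor(np.ones((n, 1, 1)))
        x = Tensor.cat([cls, tokens], axis=1)
        states: list[Tensor] = []
        for blk in self.blocks:
            x = blk(x)
            states.append(x)
        return self.norm(x), states

    # -------------------------------------------------------------- decoder
    def forward_pretrain(self, images: np.ndarray, plans: Sequence[MaskPlan]
                         ) -> tuple[Tensor, Tensor]:
        """Masked forward pass; returns (per-sample masked MSE, predictions)."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        n = images.shape[0]
        if len(plans) != n:
            raise ValueError("one MaskPlan per sample required")
        kept = np.stack([p.kept_indices for p in plans])
        masked = np.stack([p.masked_indices for p in plans])
        n_keep, n_mask = kept.shape[1], masked.shape[1]
        restore = np.argsort(np.concatenate([kept, masked], axis=1), axis=1)

        encoded, _ = self.forward_encoder(images, kept=kept)
        dec = self.decoder_embed(encoded)
        cls, patch_tok = dec[:, :1, :], dec[:, 1:, :]
        mask_tok = self.mask_token * Tensor(np.ones((n, n_mask, 1)))
        full = Tensor.cat([patch_tok, mask_tok], axis=1)
        full = full[np.arange(n)[:, None], restore]
        full = full + Tensor(self.dec_pos[None, 1:, :])
        cls = cls + Tensor(self.dec_pos[None, :1, :])
        x = Tensor.cat([cls, full], axis=1)
        for blk in self.dec_blocks:
            x = blk(x)
        pred = self.dec_head(self.dec_norm(x))[:, 1:, :]  # (N, n_patches, p^2)

        target = patchify(images, self.config.patch_size)
        err = (pred - Tensor(target)) ** 2
        masked_err = err[np.arange(n)[:, None], masked]
        l_per_sample = masked_err.reshape(n, -1).mean(axis=1)
        return l_per_sample, pred

    def encode(self, image: np.ndarray) -> TokenSequence:
        """Non-masked encoding of one slice as a :class:`TokenSequence`."""
        image = np.asarray(image, dtype=np.float64)
        if image.ndim != 2:
            raise ValueError("encode expects a single 2D slice")
        with nn.no_grad():
            final, states = self.forward_encoder(image[None])
        g = self.config.grid
        return TokenSequence(
            tokens=final.data[0],
            per_layer_states=[s.data[0] for s in states],
            patch_grid=(g, g),
        )

    def encoder_hash(self) -> str:
        """Hash over encoder-side parameters only (frozen-weight contract)."""
        enc = MAEModel.__new__(MAEModel)
        enc.patch_embed = self.patch_embed
        enc.cls_token = self.cls_token
        enc.blocks = self.blocks
        enc.norm = self.norm
        return nn.Module.weight_hash(enc)


# ------------------------------------------------------------- training


@dataclass
class MAECheckpoint:
    model: MAEModel
    config: ViTConfig
    seed: int
    epochs_done: int
    loss_curve: list[float] = field(default_factory=list)
    optimizer_state: Optional[dict] = None


def _epoch_rng(seed: int, epoch: int) -> np.random.Generator:
    return np.random.default_rng([seed, epoch])


def pretrain(
    samples: Sequence[SliceSample],
    config: ViTConfig,
    epochs: int = 30,
    batch_size: int = 48,
    lr: float = 1e-4,
    weight_decay: float = 0.01,
    w_min: float = 0.1,
    seed: int = 0,
    resume: Optional[MAECheckpoint] = None,
    verbose: bool = False,
) -> MAECheckpoint:
    """Coverage-weighted masked-reconstruction pretraining.

    Deterministic given ``seed``: shuffling and mask patterns are drawn from
    per-epoch generators keyed by (seed, epoch), so resuming from a
    checkpoint reproduces the exact continuation of a longer run.
    """
    if len(samples) == 0:
        raise ValueError("empty dataset")
    images = np.stack([s.image for s in samples])
    if images.shape[1] != config.image_size or images.shape[2] != config.image_size:
        raise ValueError(
            f"samples are {images.shape[1:]} but config expects "
            f"{config.image_size}x{config.image_size}"
        )
    alphas = np.array([s.alpha for s in samples])
    weights = coverage_weight(alphas, w_min=w_min)

    if resume is not None:
        model = resume.model
        start_epoch = resume.epochs_done
        loss_curve = list(resume.loss_curve)
    else:
        model = MAEModel(config, seed=seed)
        start_epoch = 0
        loss_curve = []
    opt = nn.AdamW(model.parameters(), lr=lr, weight_decay=weight_decay)
    if resume is not None and resume.optimizer_state is not None:
        opt.load_state_dict(resume.optimizer_state)

    n = len(samples)
    n_patches = config.n_patches
    for epoch in range(start_epoch, start_epoch + epochs):
        rng = _epoch_rng(seed, epoch)
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            plans = [
                random_mask(n_patches, config.mask_ratio,
                            seed=int(rng.integers(2**31)))
                for _ in idx
            ]
            l_per_sample, _ = model.forward_pretrain(images[idx], plans)
            w = Tensor(weights[idx])
            loss = (w * l_per_sample).sum() * (1.0 / len(idx))
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        loss_curve.append(float(np.mean(epoch_losses)))
        if verbose:
            print(f"epoch {epoch + 1}: weighted loss {loss_curve[-1]:.5f}")
    return MAECheckpoint(
        model=model,
        config=config,
        seed=seed,
        epochs_done=start_epoch + epochs,
        loss_curve=loss_curve,
        optimizer_state=opt.state_dict(),
    )


# ----------------------------------------------------------- persistence


def save_checkpoint(ckpt: MAECheckpoint, path: str | Path) -> None:
    """Weights as .npz plus a JSON sidecar (config, seed, loss curve)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = ckpt.model.state_dict()
    arrays = dict(state)
    if ckpt.optimizer_state is not None:
        arrays["__opt_t"] = np.array(ckpt.optimizer_state["t"])
        for i, m in enumerate(ckpt.optimizer_state["m"]):
            arrays[f"__opt_m{i}"] = m
        for i, v in enumerate(ckpt.optimizer_state["v"]):
            arrays[f"__opt_v{i}"] = v
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "config": asdict(ckpt.config),
        "seed": ckpt.seed,
        "epochs_done": ckpt.epochs_done,
        "loss_curve": ckpt.loss_curve,
        "weight_hash": ckpt.model.weight_hash(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> MAECheckpoint:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = ViTConfig(**sidecar["config"])
    model = MAEModel(config, seed=sidecar["seed"])
    data = np.load(path.with_suffix(".npz"))
    state = {k: data[k] for k in data.files if not k.startswith("__opt_")}
    model.load_state_dict(state)
    if model.weight_hash() != sidecar["weight_hash"]:
        raise ValueError("checkpoint weight hash mismatch")
    opt_state = None
    if "__opt_t" in data.files:
        n_par = len(model.parameters())
        opt_state = {
            "t": int(data["__opt_t"]),
            "m": [data[f"__opt_m{i}"] for i in range(n_par)],
            "v": [data[f"__opt_v{i}"] for i in range(n_par)],
        }
    return MAECheckpoint(
        model=model,
        config=config,
        seed=sidecar["seed"],
        epochs_done=sidecar["epochs_done"],
        loss_curve=list(sidecar["loss_curve"]),
        optimizer_state=opt_state,
    )
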