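"""MAE-FUnet: U-Net fused with frozen MAE encoder states, plus baselines.

A CNN U-Net backbone extracts multi-scale local features f_s(x); the frozen
MAE transformer supplies token embeddings g(x) from a set of tapped encoder
layers.  At the bottleneck and at every decoder scale, a projection aligns
the tokens with the CNN feature map (channel projection + bilinear spatial
resize) and a fusion block combines the two streams:

    h_s(x) = Fuse(f_s(x), Pi_s(g(x)))

with three interchangeable strategies — channel concatenation (followed by a
1x1 channel-reducing convolution), element-wise addition, and single-head
cross-attention with the CNN features as queries and a residual connection.
The deepest tapped layer fuses at the bottleneck, shallower taps at
progressively finer decoder scales.

Also provided: the MAE-direct baseline (a plain convolutional segmentation
head on final-layer tokens, no fusion) and the hybrid Dice + Focal + CE
segmentation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from . import nn
from .mae import MAEModel
from .nn import Tensor
from .preprocess import SliceSample

__all__ = [
    "FusionConfig",
    "HybridLossParams",
    "MAEFUnet",
    "MAEDirect",
    "SegCheckpoint",
    "dice_loss",
    "focal_loss",
    "pixel_cross_entropy",
    "hybrid_loss",
    "encode_for_fusion",
    "train_segmenter",
    "predict_segmentation",
    "dice_score_binary",
]


@dataclass(frozen=True)
class FusionConfig:
    """Fully determines the FUnet graph."""

    strategy: Literal["concat", "add", "attention", "none"] = "concat"
    tap_layers: tuple[int, ...] = (1, 3, 6, 9, 12)
    base_channels: int = 64
    depth: int = 4
    n_classes: int = 2
    image_size: int = 224

    def __post_init__(self):
        if self.strategy not in ("concat", "add", "attention", "none"):
            raise ValueError(f"unknown fusion strategy {self.strategy!r}")
        if self.strategy != "none" and len(self.tap_layers) != self.depth + 1:
            raise ValueError("need one tap layer per fusion scale (depth + 1)")
        if self.image_size % (2**self.depth):
            raise ValueError("image_size must be divisible by 2**depth")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @classmethod
    def preset(cls, name: str, **over) -> "FusionConfig":
        if name == "tiny":
            base = dict(strategy="concat", tap_layers=(1, 2, 3, 4),
                        base_channels=16, depth=3, image_size=64)
        elif name == "vitbase":
            base = dict(strategy="concat", tap_layers=(1, 3, 6, 9, 12),
                        base_channels=64, depth=4, image_size=224)
        else:
            raise ValueError(f"unknown preset {name!r}")
        base.update(over)
        return cls(**base)


@dataclass(frozen=True)
class HybridLossParams:
    """Constants of the compound Dice/Focal/CE loss."""

    epsilon: float = 1e-5
    gamma: float = 2.0
    focal_alpha: float = 0.25
    dice_weight: float = 1.0
    focal_weight: float = 1.0
    ce_weight: float = 1.0

    def __post_init__(self):
        if self.epsilon <= 0 or self.gamma < 0:
            raise ValueError("epsilon must be > 0 and gamma >= 0")


_P_FLOOR = 1e-12  # probability clamp for log terms


def _one_hot(targets: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, H, W) int labels -> (N, C, H, W) one-hot; passes one-hot through."""
    targets = np.asarray(targets)
    if targets.ndim == 4:
        return targets.astype(np.float64)
    if targets.min() < 0 or targets.max() >= n_classes:
        raise ValueError("label index out of range")
    eye = np.eye(n_classes)
    return np.moveaxis(eye[targets.astype(np.int64)], -1, 1)


def _as_probs(probs) -> Tensor:
    return probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs))


def dice_loss(probs, targets, epsilon: float = 1e-5) -> Tensor:
    """Soft Dice loss, per sample and per class (background included).

    1 - (2 sum p*g + eps) / (sum p^2 + sum g^2 + eps), averaged over classes
    then samples ("non-batch" variant: sums run within each sample).
    """
    p = _as_probs(probs)
    g = _one_hot(targets, p.shape[1])
    if g.shape != p.shape:
        raise ValueError("prediction/target shape mismatch")
    gt = Tensor(g)
    num = (p * gt).sum(axis=(2, 3)) * 2.0 + epsilon
    den = (p * p).sum(axis=(2, 3)) + Tensor((g * g).sum(axis=(2, 3))) + epsilon
    dice = num / den
    return (1.0 - dice).mean()


def focal_loss(probs, targets, gamma: float = 2.0,
               focal_alpha: float = 0.25) -> Tensor:
    """Mean over pixels of -alpha * (1 - p_true)^gamma * log(p_true)."""
    p = _as_probs(probs)
    g = _one_hot(targets, p.shape[1])
    if g.shape != p.shape:
        raise ValueError("prediction/target shape mismatch")
    p_true = (p * Tensor(g)).sum(axis=1).clip_min(_P_FLOOR)
    return ((1.0 - p_true) ** gamma * p_true.log() * (-focal_alpha)).mean()


def pixel_cross_entropy(probs, targets) -> Tensor:
    """Standard pixel-wise multi-class CE: mean over pixels of -sum_c g log p."""
    p = _as_probs(probs)
    g = _one_hot(targets, p.shape[1])
    if g.shape != p.shape:
        raise ValueError("prediction/target shape mismatch")
    logp = p.clip_min(_P_FLOOR).log()
    return -(Tensor(g) * logp).sum(axis=1).mean()


def hybrid_loss(probs, targets, params: HybridLossParams = HybridLossParams()
                ) -> Tensor:
    """Weighted sum of Dice, Focal and CE terms (unit weights by default)."""
    p = _as_probs(probs)
    total = dice_loss(p, targets, params.epsilon) * params.dice_weight
    total = total + focal_loss(p, targets, params.gamma,
                               params.focal_alpha) * params.focal_weight
    total = total + pixel_cross_entropy(p, targets) * params.ce_weight
    return total


# ------------------------------------------------------------------ model


class DoubleConv(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng, padding=1)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).relu()).relu()


class FusionBlock(nn.Module):
    """Combine a CNN feature map with projected transformer tokens at one scale."""

    def __init__(self, strategy: str, channels: int, encoder_dim: int,
                 rng: np.random.Generator):
        self.strategy = strategy
        self.proj = nn.Linear(encoder_dim, channels, rng)
        if strategy == "concat":
            self.reduce = nn.Conv2d(2 * channels, channels, 1, rng)
        elif strategy == "attention":
            self.attn = nn.CrossAttention(channels, rng)
        self.channels = channels

    def project(self, tokens: np.ndarray, out_h: int, out_w: int) -> Tensor:
        """Pi_s: channel-project patch tokens and bilinearly resize to scale s."""
        t = self.proj(Tensor(np.asarray(tokens, dtype=np.float64)))  # (N, T, C)
        n, n_tok, c = t.shape
        grid = int(round(np.sqrt(n_tok)))
        if grid * grid != n_tok:
            raise ValueError("token count must form a square grid (CLS excluded)")
        tmap = t.reshape(n, grid, grid, c).transpose(0, 3, 1, 2)
        if (grid, grid) != (out_h, out_w):
            tmap = tmap.resize_bilinear(out_h, out_w)
        return tmap

    def forward(self, f: Tensor, tokens: np.ndarray) -> Tensor:
        n, c, h, w = f.shape
        if self.strategy == "attention":
            t = self.proj(Tensor(np.asarray(tokens, dtype=np.float64)))
            q = f.reshape(n, c, h * w).transpose(0, 2, 1)
            out = self.attn(q, t)
            return f + out.transpose(0, 2, 1).reshape(n, c, h, w)
        tmap = self.project(tokens, h, w)
        if self.strategy == "add":
            return f + tmap
        return self.reduce(Tensor.cat([f, tmap], axis=1))


class MAEFUnet(nn.Module):
    """U-Net backbone with optional transformer fusion at depth+1 scales.

    With ``strategy='none'`` this is the plain U-Net ablation running through
    the same code path.
    """

    def __init__(self, fusion: FusionConfig, encoder_dim: int = 768,
                 encoder_layers: int = 12, seed: int = 0):
        if fusion.strategy != "none" and max(fusion.tap_layers) > encoder_layers:
            raise ValueError("tap layer exceeds encoder depth")
        rng = np.random.default_rng(seed)
        self.fusion_config = fusion
        d, base = fusion.depth, fusion.base_channels
        enc_ch = [base * 2**s for s in range(d)]  # encoder stages
        bott_ch = base * 2**d
        ins = [1] + enc_ch[:-1]
        self.enc_blocks = [DoubleConv(i, o, rng) for i, o in zip(ins, enc_ch)]
        self.bottleneck = DoubleConv(enc_ch[-1], bott_ch, rng)
        # decoder, deep to shallow
        dec_ch = [base * 2 ** (d - 1 - i) for i in range(d)]
        ups, decs = [], []
        prev = bott_ch
        for c in dec_ch:
            ups.append(nn.Conv2d(prev, c, 3, rng, padding=1))
            decs.append(DoubleConv(2 * c, c, rng))
            prev = c
        self.up_convs = ups
        self.dec_blocks = decs
        self.head = nn.Conv2d(base, fusion.n_classes, 1, rng)
        if fusion.strategy != "none":
            taps = sorted(fusion.tap_layers)
            site_ch = [bott_ch] + dec_ch  # deepest tap first
            self.fusion_blocks = [
                FusionBlock(fusion.strategy, c, encoder_dim, rng)
                for c in site_ch
            ]
            self.site_taps = list(reversed(taps))  # tap per site, deep->shallow
        else:
            self.fusion_blocks = []
            self.site_taps = []

    def unet_features(self, images: np.ndarray) -> list[np.ndarray]:
        """CNN encoder feature maps (one per stage) plus the bottleneck.

        Channel counts follow the doubling ladder base*2^0 ... base*2^depth
        with spatial dims halving per stage.
        """
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        if images.ndim == 3:
            images = images[:, None]
        if images.shape[-1] % (2**self.fusion_config.depth):
            raise ValueError("input size not divisible by 2**depth")
        feats = []
        from . import nn as _nn

        with _nn.no_grad():
            x = Tensor(images)
            for blk in self.enc_blocks:
                x = blk(x)
                feats.append(x.data)
                x = x.maxpool2x2()
            feats.append(self.bottleneck(x).data)
        return feats

    def forward(self, images: np.ndarray,
                token_states: Optional[dict[int, np.ndarray]] = None) -> Tensor:
        """Return segmentation logits (N, n_classes, H, W)."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        if images.ndim == 3:
            images = images[:, None]
        if images.shape[-1] != self.fusion_config.image_size:
            raise ValueError("input size does not match config")
        if self.fusion_blocks and token_states is None:
            raise ValueError("fusion model requires encoder token states")
        x = Tensor(images)
        skips = []
        for blk in self.enc_blocks:
            x = blk(x)
            skips.append(x)
            x = x.maxpool2x2()
        x = self.bottleneck(x)
        if self.fusion_blocks:
            x = self.fusion_blocks[0](x, token_states[self.site_taps[0]])
        for i, (up, dec) in enumerate(zip(self.up_convs, self.dec_blocks)):
            x = up(x.upsample_nearest2x())
            x = dec(Tensor.cat([skips[-1 - i], x], axis=1))
            if self.fusion_blocks:
                x = self.fusion_blocks[i + 1](x, token_states[self.site_taps[i + 1]])
        return self.head(x)


class MAEDirect(nn.Module):
    """Segmentation head directly on final-layer MAE tokens (no fusion).

    Tokens are reshaped to their spatial grid and upsampled back to full
    resolution through conv + 2x-upsample blocks, then classified per pixel.
    """

    def __init__(self, encoder_dim: int, grid: int, image_size: int,
                 n_classes: int, seed: int = 0):
        n_up = int(np.log2(image_size / grid))
        if grid * 2**n_up != image_size:
            raise ValueError("image_size must be grid * 2**k")
        rng = np.random.default_rng(seed)
        chans = [max(encoder_dim // 2 ** (i + 1), 8) for i in range(n_up)]
        self.blocks = []
        prev = encoder_dim
        for c in chans:
            self.blocks.append(nn.Conv2d(prev, c, 3, rng, padding=1))
            prev = c
        self.head = nn.Conv2d(prev, n_classes, 1, rng)
        self.grid = grid

    def forward(self, tokens: np.ndarray) -> Tensor:
        """tokens: (N, T, d) final-layer patch tokens (CLS excluded)."""
        tokens = np.asarray(tokens, dtype=np.float64)
        n, t, d = tokens.shape
        if t != self.grid**2:
            raise ValueError("token count does not match grid")
        x = Tensor(tokens).reshape(n, self.grid, self.grid, d).transpose(0, 3, 1, 2)
        for conv in self.blocks:
            x = conv(x).relu().upsample_nearest2x()
        return self.head(x)


# ----------------------------------------------------------- train / eval


def encode_for_fusion(model: MAEModel, images: np.ndarray,
                      tap_layers: Sequence[int], batch_size: int = 32
                      ) -> dict[int, np.ndarray]:
    """Frozen, non-masked encoder pass; patch-token states per tapped layer.

    Layer indices are 1-based block outputs; key 0 holds the final-normed
    tokens (for the MAE-direct head).  CLS is excluded everywhere.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    e = model.config.encoder_layers
    for tap in tap_layers:
        if not 1 <= tap <= e:
            raise ValueError(f"tap layer {tap} exceeds encoder depth {e}")
    chunks: dict[int, list[np.ndarray]] = {tap: [] for tap in tap_layers}
    chunks[0] = []
    with nn.no_grad():
        for lo in range(0, len(images), batch_size):
            final, states = model.forward_encoder(images[lo : lo + batch_size])
            for tap in tap_layers:
                chunks[tap].append(states[tap - 1].data[:, 1:, :])
            chunks[0].append(final.data[:, 1:, :])
    return {k: np.concatenate(v, axis=0) for k, v in chunks.items()}


def dice_score_binary(pred: np.ndarray, truth: np.ndarray) -> float:
    """Plain Dice on binary masks (both-empty convention: 1.0)."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, truth).sum() / denom)


@dataclass
class SegCheckpoint:
    model: nn.Module
    fusion: FusionConfig
    seed: int
    loss_curve: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)


def _targets_of(samples: Sequence[SliceSample], target: str) -> np.ndarray:
    if target == "brain_mask":
        return np.stack([s.brain_mask for s in samples]).astype(np.int64)
    return np.stack([s.labels for s in samples]).astype(np.int64)


def train_segmenter(
    train_samples: Sequence[SliceSample],
    mae_model: Optional[MAEModel],
    fusion: FusionConfig,
    target: str = "brain_mask",
    seed: int = 0,
    epochs: int = 30,
    batch_size: int = 8,
    lr: float = 1e-4,
    weight_decay: float = 0.01,
    loss_params: HybridLossParams = HybridLossParams(),
    val_samples: Sequence[SliceSample] = (),
    verbose: bool = False,
) -> SegCheckpoint:
    """Train the FUnet (or plain U-Net) on labeled slices with the hybrid loss.

    The MAE encoder stays frozen: its token states are computed once up
    front with gradients disabled and reused every epoch; only CNN, fusion
    and head parameters enter the optimizer.
    """
    if len(train_samples) == 0:
        raise ValueError("empty training set")
    images = np.stack([s.image for s in train_samples])
    targets = _targets_of(train_samples, target)
    if targets.max() >= fusion.n_classes:
        raise ValueError("label index >= n_classes")

    needs_tokens = fusion.strategy != "none"
    if needs_tokens and mae_model is None:
        raise ValueError("fusion strategies require a pretrained encoder")
    cache = (
        encode_for_fusion(mae_model, images, fusion.tap_layers)
        if needs_tokens else None
    )
    val_cache = None
    if val_samples:
        val_imgs = np.stack([s.image for s in val_samples])
        val_true = _targets_of(val_samples, target)
        if needs_tokens:
            val_cache = encode_for_fusion(mae_model, val_imgs, fusion.tap_layers)

    enc_dim = mae_model.config.encoder_dim if mae_model is not None else 768
    enc_layers = mae_model.config.encoder_layers if mae_model is not None else 12
    model = MAEFUnet(fusion, encoder_dim=enc_dim, encoder_layers=enc_layers,
                     seed=seed)
    opt = nn.AdamW(model.parameters(), lr=lr, weight_decay=weight_decay)

    n = len(train_samples)
    ckpt = SegCheckpoint(model=model, fusion=fusion, seed=seed)
    for epoch in range(epochs):
        rng = np.random.default_rng([seed, epoch])
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            batch_tokens = (
                {tap: cache[tap][idx] for tap in fusion.tap_layers}
                if needs_tokens else None
            )
            logits = model(images[idx], batch_tokens)
            probs = logits.softmax(axis=1)
            loss = hybrid_loss(probs, targets[idx], loss_params)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        ckpt.loss_curve.append(float(np.mean(losses)))
        if val_samples:
            pred = predict_segmentation(model, val_imgs, val_cache)
            dices = [
                dice_score_binary(pred[i] > 0, val_true[i] > 0)
                for i in range(len(val_samples))
            ]
            ckpt.val_dice.append(float(np.mean(dices)))
        if verbose:
            msg = f"epoch {epoch + 1}: loss {ckpt.loss_curve[-1]:.4f}"
            if ckpt.val_dice:
                msg += f", val dice {ckpt.val_dice[-1]:.4f}"
            print(msg)
    return ckpt


def predict_segmentation(model: MAEFUnet, images: np.ndarray,
                         token_cache: Optional[dict[int, np.ndarray]] = None,
                         batch_size: int = 16) -> np.ndarray:
    """Argmax label maps (ties break toward the lowest class index)."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    out = []
    taps = model.fusion_config.tap_layers if model.fusion_blocks else ()
    with nn.no_grad():
        for lo in range(0, len(images), batch_size):
            tok = (
                {tap: token_cache[tap][lo : lo + batch_size] for tap in taps}
                if model.fusion_blocks else None
            )
            logits = model(images[lo : lo + batch_size], tok)
            out.append(np.argmax(logits.data, axis=1))
    return np.concatenate(out, axis=0)
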