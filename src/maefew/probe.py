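"""Frozen-encoder linear probing for MRI sequence classification.

The pretrained encoder is used as a fixed feature extractor: each slice is
encoded without masking and the final-layer-normed CLS embedding summarizes
the image.  A linear head (C x d weights plus C biases, so C*(d+1)
trainable parameters) is trained with cross-entropy; encoder weights are
never updated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp, softmax as _softmax

from . import nn
from .mae import MAEModel
from .nn import Tensor
from .preprocess import SliceSample

__all__ = [
    "ProbeHead",
    "extract_cls",
    "cross_entropy",
    "train_probe",
    "predict",
]


@dataclass
class ProbeHead:
    """Linear classifier over CLS embeddings."""

    W: np.ndarray  # (C, d)
    b: np.ndarray  # (C,)
    class_names: list[str] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return self.W.size + self.b.size

    def logits(self, embeddings: np.ndarray) -> np.ndarray:
        return np.atleast_2d(embeddings) @ self.W.T + self.b


def extract_cls(model: MAEModel, images: np.ndarray,
                batch_size: int = 64) -> np.ndarray:
    """CLS embeddings from the final encoder layer, no masking, no gradient."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    if images.shape[-1] != model.config.image_size:
        raise ValueError("image size does not match encoder config")
    out = []
    with nn.no_grad():
        for lo in range(0, len(images), batch_size):
            tokens, _ = model.forward_encoder(images[lo : lo + batch_size])
            out.append(tokens.data[:, 0, :])
    return np.concatenate(out, axis=0)


def cross_entropy(logits: np.ndarray, label) -> float:
    """Multi-class cross-entropy  -z_y + log sum_j exp(z_j), log-sum-exp stabilized.

    Accepts one logit vector with an integer label, or a batch with a label
    vector (returns the mean).
    """
    z = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite logits")
    y = np.atleast_1d(np.asarray(label, dtype=np.int64))
    c = z.shape[1]
    if np.any(y < 0) or np.any(y >= c):
        raise ValueError("label out of range")
    losses = -z[np.arange(len(y)), y] + logsumexp(z, axis=1)
    return float(np.mean(losses))


def train_probe(
    train_samples: Sequence[SliceSample],
    model: MAEModel,
    n_classes: int,
    seed: int = 0,
    epochs: int = 2000,
    lr: float = 1e-3,
    weight_decay: float = 0.0,
    class_names: Sequence[str] | None = None,
    verbose: bool = False,
) -> tuple[ProbeHead, dict]:
    """Train only the linear head on frozen CLS features (full batch, AdamW).

    Features are extracted once up front; the encoder takes no gradient and
    its weights are untouched.  Deterministic under a fixed seed.

    CLS embeddings have small variance around a large mean direction, so the
    features are standardized (per-dimension z-score on training statistics)
    before the logistic fit; the standardization is folded back into the
    returned W and b, so the head remains a plain linear map with C*(d+1)
    parameters.  The default learning rate is raised above the reference
    1e-4 because training here is full-batch on a handful of slices.
    """
    if len(train_samples) == 0:
        raise ValueError("empty training manifest")
    labels = np.array([s.sequence_label for s in train_samples], dtype=np.int64)
    if np.any(labels < 0) or np.any(labels >= n_classes):
        raise ValueError("sequence_label out of range")
    present = np.unique(labels)
    log: dict = {"warnings": [], "loss_curve": []}
    if len(present) < n_classes:
        missing = sorted(set(range(n_classes)) - set(present.tolist()))
        log["warnings"].append(f"classes absent from training data: {missing}")

    feats = extract_cls(model, np.stack([s.image for s in train_samples]))
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd < 1e-8] = 1.0
    feats = (feats - mu) / sd
    d = feats.shape[1]
    rng = np.random.default_rng(seed)
    head_w = nn.Parameter(rng.normal(0, 0.01, size=(d, n_classes)))
    head_b = nn.Parameter(np.zeros(n_classes))
    opt = nn.AdamW([head_w, head_b], lr=lr, weight_decay=weight_decay)
    x = Tensor(feats)
    onehot = np.eye(n_classes)[labels]
    for _ in range(epochs):
        logits = x @ head_w + head_b
        shift = logits.data.max(axis=1, keepdims=True)  # detached, exact identity
        lse = (logits - Tensor(shift)).exp().sum(axis=1, keepdims=True).log() + Tensor(shift)
        logp = logits - lse
        loss = -(Tensor(onehot) * logp).sum() * (1.0 / len(labels))
        opt.zero_grad()
        loss.backward()
        opt.step()
        log["loss_curve"].append(loss.item())
        if verbose and len(log["loss_curve"]) % 50 == 0:
            print(f"probe step {len(log['loss_curve'])}: CE {loss.item():.4f}")
    # fold the feature standardization into the linear map:
    # W' z + b' with z = (x - mu)/sd  ==  (W'/sd) x + (b' - W' mu/sd)
    w_std = head_w.data.T / sd[None, :]
    b_std = head_b.data - w_std @ mu
    head = ProbeHead(
        W=w_std,
        b=b_std,
        class_names=list(class_names) if class_names else [],
    )
    return head, log


def predict(head: ProbeHead, embeddings: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and softmax probabilities.

    Ties on equal logits break toward the lowest class index (argmax
    convention), keeping predictions deterministic.
    """
    embeddings = np.atleast_2d(embeddings)
    if embeddings.shape[1] != head.W.shape[1]:
        raise ValueError("embedding dimension does not match head")
    z = head.logits(embeddings)
    probs = _softmax(z, axis=1)
    return np.argmax(z, axis=1), probs
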