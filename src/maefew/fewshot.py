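"""Few-shot dataset construction protocols.

Three protocols mirror how scarce annotation shows up in practice:

* **slice-level sampling** for sequence classification: n random slices per
  sequence, train and test disjoint at the volume level;
* **sparse stride sampling** for skull stripping: keep every k-th slice of a
  single subject's volume (1-based multiples of k), simulating thick-slice
  or sparsely annotated acquisitions;
* **volume-level sampling** for anatomical segmentation: sample whole
  volumes, then remap each 3D volume to 2D slices along the sagittal,
  coronal and axial axes, dropping slices with no meaningful mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .phantom import PhantomVolume, brain_coverage
from .preprocess import AXES, SliceSample, clamp_normalize, resize_to_input

__all__ = [
    "FewShotSpec",
    "Split",
    "stride_sample",
    "remap_volume_to_slices",
    "build_classification_split",
    "build_segmentation_split",
    "split_manifest",
]


@dataclass(frozen=True)
class FewShotSpec:
    """Configuration of a few-shot split."""

    task: Literal["classification", "skull_strip", "anatomy"] = "classification"
    n_slices_per_sequence: int = 10
    stride_k: int = 7
    n_volumes: int = 7
    axes: tuple[str, ...] = ("sagittal", "coronal", "axial")
    min_foreground: int = 1
    image_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.stride_k < 1:
            raise ValueError("stride_k must be >= 1")
        if self.min_foreground < 0:
            raise ValueError("min_foreground must be >= 0")
        bad = set(self.axes) - set(AXES)
        if bad:
            raise ValueError(f"unknown axes: {sorted(bad)}")


@dataclass
class Split:
    """A few-shot train/test split with its manifest."""

    train: list[SliceSample]
    test: list[SliceSample]
    class_names: list[str] = field(default_factory=list)

    @property
    def manifest(self) -> pd.DataFrame:
        return split_manifest(self)


def split_manifest(split: Split) -> pd.DataFrame:
    rows = []
    for part, samples in (("train", split.train), ("test", split.test)):
        for s in samples:
            rows.append(
                {
                    "volume_id": s.provenance[0],
                    "axis": s.provenance[1],
                    "index": s.provenance[2],
                    "sequence": s.sequence,
                    "split": part,
                    "alpha": s.alpha,
                }
            )
    return pd.DataFrame(rows, columns=["volume_id", "axis", "index",
                                       "sequence", "split", "alpha"])


def stride_sample(n_slices_on_axis: int, k: int) -> list[int]:
    """Indices of every k-th slice: 1-based multiples of k as 0-based indices.

    Returns {k-1, 2k-1, ...}; the count is floor(n/k).  ``k > n`` yields an
    empty selection with a warning rather than an error.
    """
    if n_slices_on_axis < 1:
        raise ValueError("n_slices_on_axis must be >= 1")
    if k < 1:
        raise ValueError("stride k must be >= 1")
    if k > n_slices_on_axis:
        warnings.warn(
            f"stride {k} exceeds axis length {n_slices_on_axis}: empty selection",
            stacklevel=2,
        )
        return []
    return list(range(k - 1, n_slices_on_axis, k))


def _take_slice(arr: np.ndarray, axis_idx: int, i: int) -> np.ndarray:
    return np.take(arr, i, axis=axis_idx)


def remap_volume_to_slices(
    volume: PhantomVolume,
    axes: Sequence[str] = ("sagittal", "coronal", "axial"),
    min_foreground: int = 1,
    image_size: Optional[int] = None,
    stride_k: int = 1,
    sequence_label: Optional[int] = None,
    normalize: bool = True,
) -> list[SliceSample]:
    """Extract 2D slices along the requested anatomical axes.

    The volume intensity is normalized once (percentile clamp + max-min)
    before slicing.  Slices whose label foreground pixel count is below
    ``min_foreground`` are dropped.  ``stride_k`` applies the sparse-slice
    rule independently along each requested axis.
    """
    if min_foreground > 0 and volume.labels is None:
        raise ValueError("labels are required when min_foreground > 0")
    image = clamp_normalize(volume.image) if normalize else volume.image
    out: list[SliceSample] = []
    for axis_name in axes:
        axis_idx = AXES[axis_name]
        n = image.shape[axis_idx]
        for i in stride_sample(n, stride_k):
            lab = _take_slice(volume.labels, axis_idx, i)
            if int(np.count_nonzero(lab)) < min_foreground:
                continue
            img = _take_slice(image, axis_idx, i)
            msk = _take_slice(volume.brain_mask, axis_idx, i)
            if image_size is not None:
                img, msk, lab = resize_to_input(img, msk, lab, size=image_size)
            out.append(
                SliceSample(
                    image=img,
                    brain_mask=msk,
                    labels=lab,
                    sequence=volume.sequence,
                    sequence_label=sequence_label,
                    alpha=brain_coverage(msk),
                    provenance=(volume.volume_id, axis_name, i),
                )
            )
    return out


def build_classification_split(
    volumes_by_sequence: dict[str, list[PhantomVolume]],
    n_slices_per_sequence: int,
    seed: int,
    axes: Sequence[str] = ("axial",),
    min_foreground: int = 1,
    image_size: Optional[int] = None,
    max_test_slices_per_sequence: Optional[int] = None,
    n_train_volumes: int = 3,
) -> Split:
    """Slice-level few-shot split for sequence classification.

    For each sequence the available volumes are shuffled; the first
    ``n_train_volumes`` (fewer if that already exceeds what is needed or
    available) form the train pool from which ``n_slices_per_sequence``
    slices are sampled without replacement — mirroring slice sourcing from
    several patients/cohorts — and every remaining volume contributes to
    the test set, so no volume appears on both sides.
    """
    class_names = sorted(volumes_by_sequence)
    rng = np.random.default_rng(seed)
    train: list[SliceSample] = []
    test: list[SliceSample] = []
    for label, seq in enumerate(class_names):
        vols = volumes_by_sequence[seq]
        if not vols:
            raise ValueError(f"no volumes available for sequence {seq}")
        order = rng.permutation(len(vols))
        pools: list[list[SliceSample]] = []
        total = 0
        split_at = 0
        for split_at, vi in enumerate(order, start=1):
            slices = remap_volume_to_slices(
                vols[vi], axes=axes, min_foreground=min_foreground,
                image_size=image_size, sequence_label=label,
            )
            pools.append(slices)
            total += len(slices)
            if total >= n_slices_per_sequence and split_at >= min(
                n_train_volumes, len(vols) - 1 or 1
            ):
                break
        if total < n_slices_per_sequence:
            raise ValueError(
                f"sequence {seq}: requested {n_slices_per_sequence} slices "
                f"but only {total} are available"
            )
        pool = [s for p in pools for s in p]
        pick = rng.choice(len(pool), size=n_slices_per_sequence, replace=False)
        train.extend(pool[i] for i in sorted(pick))
        test_slices: list[SliceSample] = []
        for vi in order[split_at:]:
            test_slices.extend(
                remap_volume_to_slices(
                    vols[vi], axes=axes, min_foreground=min_foreground,
                    image_size=image_size, sequence_label=label,
                )
            )
        if max_test_slices_per_sequence is not None and \
                len(test_slices) > max_test_slices_per_sequence:
            keep = rng.choice(len(test_slices), size=max_test_slices_per_sequence,
                              replace=False)
            test_slices = [test_slices[i] for i in sorted(keep)]
        test.extend(test_slices)
    return Split(train=train, test=test, class_names=class_names)


def build_segmentation_split(
    volumes: Sequence[PhantomVolume],
    spec: FewShotSpec,
) -> Split:
    """Few-shot split for segmentation.

    ``skull_strip``: one training volume per sequence with sparse stride
    sampling (``spec.stride_k``) along the requested axes; the remaining
    volumes form the test set at stride 1.

    ``anatomy``: ``spec.n_volumes`` whole training volumes, tri-axially
    remapped to slices; the rest are test volumes.
    """
    if spec.task not in ("skull_strip", "anatomy"):
        raise ValueError(f"not a segmentation task: {spec.task}")
    rng = np.random.default_rng(spec.seed)
    train: list[SliceSample] = []
    test: list[SliceSample] = []
    if spec.task == "skull_strip":
        by_seq: dict[str, list[PhantomVolume]] = {}
        for v in volumes:
            by_seq.setdefault(v.sequence, []).append(v)
        for seq in sorted(by_seq):
            vols = by_seq[seq]
            order = rng.permutation(len(vols))
            train_vol = vols[order[0]]
            train.extend(
                remap_volume_to_slices(
                    train_vol, axes=spec.axes, min_foreground=spec.min_foreground,
                    image_size=spec.image_size, stride_k=spec.stride_k,
                )
            )
            for vi in order[1:]:
                test.extend(
                    remap_volume_to_slices(
                        vols[vi], axes=spec.axes,
                        min_foreground=spec.min_foreground,
                        image_size=spec.image_size,
                    )
                )
    else:
        if spec.n_volumes > len(volumes):
            raise ValueError(
                f"requested {spec.n_volumes} training volumes but only "
                f"{len(volumes)} are available"
            )
        order = rng.permutation(len(volumes))
        for vi in order[: spec.n_volumes]:
            train.extend(
                remap_volume_to_slices(
                    volumes[vi], axes=spec.axes,
                    min_foreground=spec.min_foreground,
                    image_size=spec.image_size,
                )
            )
        for vi in order[spec.n_volumes :]:
            test.extend(
                remap_volume_to_slices(
                    volumes[vi], axes=spec.axes,
                    min_foreground=spec.min_foreground,
                    image_size=spec.image_size,
                )
            )
    return Split(train=train, test=test)
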