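"""Slice preprocessing: normalization, resizing, augmentation, resampling.

The preprocessing chain is intentionally light — percentile clamping,
max-min normalization to [0, 1], zero-padding to square, resize to the model
input size — with no registration, bias-field correction or reorientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import scipy.ndimage as ndi
from skimage.transform import resize as _sk_resize

from .phantom import PhantomVolume, brain_coverage

__all__ = [
    "SliceSample",
    "clamp_normalize",
    "resize_to_input",
    "augment",
    "resample_isotropic",
    "AXES",
]

AXES = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class SliceSample:
    """One preprocessed 2D slice with optional ground truth.

    ``alpha`` is the brain-coverage fraction of the slice; ``provenance``
    records (volume id, axis name, slice index) for leakage bookkeeping.
    """

    image: np.ndarray
    brain_mask: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    sequence: Optional[str] = None
    sequence_label: Optional[int] = None
    alpha: float = 0.0
    provenance: tuple[str, str, int] = ("", "", -1)

    def __post_init__(self):
        if self.image.ndim != 2:
            raise ValueError("SliceSample.image must be 2D")
        for m in (self.brain_mask, self.labels):
            if m is not None and m.shape != self.image.shape:
                raise ValueError("masks must share the image shape")


def clamp_normalize(image: np.ndarray, low: float = 0.1, high: float = 99.9
                    ) -> np.ndarray:
    """Clip to the [low, high] percentiles then max-min normalize to [0, 1].

    Percentiles use linear interpolation between order statistics.  A
    constant input (zero dynamic range) maps to all zeros.  Works on arrays
    of any dimensionality; for 3D volumes the percentiles are taken over the
    whole volume (keeping inter-slice contrast consistent).
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains NaN or Inf")
    lo, hi = np.percentile(image, [low, high])
    if hi <= lo:
        return np.zeros_like(image)
    clipped = np.clip(image, lo, hi)
    return (clipped - lo) / (hi - lo)


def _pad_to_square(arr: np.ndarray) -> np.ndarray:
    h, w = arr.shape
    if h == w:
        return arr
    n = max(h, w)
    ph, pw = n - h, n - w
    return np.pad(arr, ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)))


def _resize2d(arr: np.ndarray, size: int, order: int) -> np.ndarray:
    if arr.shape == (size, size):
        return arr.astype(np.float64) if order > 0 else arr
    out = _sk_resize(
        arr.astype(np.float64), (size, size), order=order,
        mode="edge", anti_aliasing=False, preserve_range=True,
    )
    return out


def resize_to_input(image: np.ndarray, mask: np.ndarray | None = None,
                    labels: np.ndarray | None = None, size: int = 224):
    """Pad to square then resize to ``size``x``size``.

    The image uses bilinear interpolation; masks/labels use nearest-neighbor
    so the label set is preserved.  Returns the image alone, or a tuple with
    whichever masks were supplied.
    """
    if np.asarray(image).ndim != 2:
        raise ValueError("resize_to_input expects a 2D image")
    out_img = _resize2d(_pad_to_square(np.asarray(image, dtype=np.float64)), size, 1)
    results = [out_img]
    for m in (mask, labels):
        if m is not None:
            if m.shape != image.shape:
                raise ValueError("mask shape must match image shape")
            r = _resize2d(_pad_to_square(np.asarray(m)), size, 0)
            results.append(r.astype(m.dtype))
    if len(results) == 1:
        return out_img
    return tuple(results)


def augment(sample: SliceSample, seed: int, enabled: bool = True,
            max_rotation_deg: float = 15.0, flip_p: float = 0.5,
            crop_scale: tuple[float, float] = (0.8, 1.0)) -> SliceSample:
    """Seeded random rotation, flips, and crop-then-resize.

    The same geometric transform is applied jointly to the image and any
    masks; the coverage fraction ``alpha`` is recomputed from the augmented
    brain mask (cropping changes coverage).
    """
    if not enabled:
        return sample
    rng = np.random.default_rng(seed)
    angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
    flip_h = rng.random() < flip_p
    flip_v = rng.random() < flip_p
    scale = rng.uniform(*crop_scale)

    size = sample.image.shape[0]
    crop = max(8, int(round(size * scale)))
    max_off = size - crop
    off_r = int(rng.integers(0, max_off + 1)) if max_off > 0 else 0
    off_c = int(rng.integers(0, max_off + 1)) if max_off > 0 else 0

    def geom(arr: np.ndarray, order: int) -> np.ndarray:
        out = ndi.rotate(arr.astype(np.float64), angle, reshape=False,
                         order=order, mode="constant", cval=0.0)
        if flip_h:
            out = out[:, ::-1]
        if flip_v:
            out = out[::-1, :]
        out = out[off_r : off_r + crop, off_c : off_c + crop]
        return _resize2d(out, size, order)

    image = np.clip(geom(sample.image, 1), 0.0, 1.0)
    mask = None
    labels = None
    if sample.brain_mask is not None:
        mask = geom(sample.brain_mask, 0).astype(sample.brain_mask.dtype)
    if sample.labels is not None:
        labels = geom(sample.labels, 0).astype(sample.labels.dtype)
    alpha = brain_coverage(mask) if mask is not None else sample.alpha
    return replace(sample, image=image, brain_mask=mask, labels=labels, alpha=alpha)


def resample_isotropic(volume: PhantomVolume, order: int = 1) -> PhantomVolume:
    """Resample a volume to isotropic voxels (the smallest voxel size).

    Axis lengths scale by the voxel-size ratio; the image is interpolated
    continuously and masks/labels nearest-neighbor.
    """
    vox = np.asarray(volume.voxel_size_mm, dtype=np.float64)
    if np.any(vox <= 0):
        raise ValueError("voxel sizes must be positive")
    target = vox.min()
    factors = vox / target
    if np.allclose(factors, 1.0):
        return volume
    image = ndi.zoom(volume.image, factors, order=order, mode="nearest")
    mask = ndi.zoom(volume.brain_mask, factors, order=0, mode="nearest")
    labels = ndi.zoom(volume.labels, factors, order=0, mode="nearest")
    return PhantomVolume(
        image=np.clip(image, 0.0, 1.0),
        brain_mask=mask.astype(volume.brain_mask.dtype),
        labels=labels.astype(volume.labels.dtype),
        voxel_size_mm=(float(target),) * 3,
        sequence=volume.sequence,
        volume_id=volume.volume_id,
    )
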