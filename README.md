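# maefew

Few-shot deployment of masked-autoencoder (MAE) MRI transformers for brain
imaging tasks, at desk scale.

Clinical neuroimaging rarely offers the thousands of annotated scans that
transformers want. One practical answer is to pretrain a vision transformer
once, self-supervised, on large unlabeled MRI collections, then reuse the
frozen encoder for each downstream task with a tiny trainable head. This
package implements that workflow end to end:

* **Coverage-weighted MAE pretraining** — mask 75% of image patches and
  reconstruct them; each slice's masked-patch MSE l̃ᵢ is weighted by its
  brain-coverage fraction αᵢ, `L = (1/N) Σ wᵢ l̃ᵢ` with
  `wᵢ = 0.1 + 0.9·αᵢ`, so background-dominated slices pull less on the
  representation.
* **MAE-classify** — frozen-encoder linear probing on the CLS token for MRI
  sequence classification (T1 / T2 / FLAIR / PD…), with exactly `C(d+1)`
  trainable parameters.
* **MAE-FUnet** — a U-Net whose bottleneck and decoder stages are fused
  with frozen transformer token states, `h_s = Fuse(f_s, Π_s(g(x)))`, via
  concatenation, addition, or cross-attention, trained with the hybrid
  `Dice + Focal + CE` loss for skull stripping and multi-class anatomical
  segmentation. An MAE-direct baseline (tokens → conv head, no fusion) and
  a plain U-Net ablation share the code path.
* **Few-shot protocols** — slice-level sampling for classification,
  sparse stride-k slice sampling for skull stripping (every k-th slice,
  floor(n/k) slices from an n-slice axis), volume-level sampling with
  tri-axial remapping and empty-mask filtering for anatomy.
* **Metrics** — micro/macro/weighted F1 from one-vs-rest confusion counts,
  per-class Dice/IoU, and mean ± population-STD stability summaries for
  sweeps.

Real MRI cohorts are access-controlled and huge, so the package bundles a
synthetic brain-phantom generator (concentric ellipsoid anatomy, skull
ring, four sequence contrasts, exact masks and labels) that makes every
stage testable on one CPU. The neural networks run on a small numpy
autograd engine included in the package (`maefew.nn`).

## Worked example

`examples/03_sequence_classification_probe.py` pretrains a tiny encoder
(64×64 slices, 8×8 patches, 4 layers, width 64) on 320 phantom slices, then
trains a linear probe with 10 labeled slices per sequence from a disjoint
cohort:

```
trainable parameters: 260 (encoder frozen)
held-out accuracy 96.67%  macro-F1 96.65%  on 120 slices
```

260 = C(d+1) for C=4 sequences at d=64 — the only parameters that train;
97% of 120 held-out slices from unseen subjects are assigned the correct
acquisition sequence. `examples/04_skull_stripping_funet.py` continues with
the fusion segmenter trained on ~20 stride-7 slices:

```
training on 20 stride-7 slices (one volume per sequence)
test Dice 91.55%  IoU 86.22% on 48 held-out slices
```

A Dice of 92% means the predicted brain mask and the ground-truth mask
overlap almost pixel-for-pixel despite the tiny training set. The other
examples cover phantom generation, pretraining curves, and the metric /
stability toolbox; each prints what its numbers mean.

A thin CLI wraps the same pipelines:

```bash
maefew phantom out/ --seed 0        # NIfTI volumes + manifest
maefew pretrain --preset tiny       # coverage-weighted MAE
maefew probe --n-slices 10          # few-shot sequence classification
maefew segment --task skull_strip --stride 7
maefew sweep stride --values 4,5,6,7,8,9,10
```

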