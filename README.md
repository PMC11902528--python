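# amodalgrape

Occlusion-aware instance segmentation and amodal mask completion for
cluster fruit (grape-style) imagery.

In vineyard phenotyping, clusters hide one another: counts and areas
measured from visible masks systematically underestimate the crop. This
package implements a de-occlusion pipeline that predicts the *complete*
silhouette of a partially hidden cluster — its amodal mask — without ever
having amodal annotations, and decides, for any overlapping pair, which
instance is in front. It is aimed at researchers in plant phenotyping and
agricultural computer vision who want the individual mechanisms
(incoherent-region supervision, occlusion synthesis, mask completion,
occlusion-relation inference) as tested, composable library code.

## What is inside

**Incoherent-region supervision** (`amodalgrape.incoherent`). Resizing an
annotation mask down for training and back up corrupts pixels near
boundaries — the *incoherent region* `M_inc = D(m ⊕ U(D(m)))` for
bilinear down/up operators `D`, `U`. Its restriction to points where two
distinct instances meet (decided by three symmetric pixel-pair samples per
point) isolates exactly the overlap seams that matter for de-occlusion.
Per-proposal supervision triples feed a dual-decoder head.

**Dual-decoder heads with pixel affinity learning**
(`amodalgrape.heads`). A mask decoder (28×28 output, BCE loss) and an
incoherent-region decoder (28 or 56 px output, dice+BCE plus a λ-weighted
term restricted to the local incoherent region, λ = 2) share information
through a pixel affinity learning module: a 2c→c→2c bottleneck over the
concatenated features, a two-way softmax reweighting per position and
channel, and squeeze-and-excitation feedback added to both branches. A
boundary-supervised baseline (thin Laplacian boundary targets) is included
for comparison.

**Overlapping-cover occlusion synthesis** (`amodalgrape.synthesis`).
Training triples (occluded, occluder, intact) are manufactured from a pool
of complete instances under 8 directional cases with an overlap ratio
β ∈ (0.2, 0.85], a height filter (0.9 < h_occ/h_occder < 1.2), an
occlusion-rate filter (ε = 1 − |visible|/|intact| > 0.1 with β-retry), and
*reverse synthesis*: identity samples that teach the completer not to
inflate instances that are actually in front. A random-cover baseline is
provided.

**Amodal completion and the occlusion relation** (`amodalgrape.amodal`).
A U-Net consumes the visible mask and the occluder mask as two channels
and predicts the complete mask, trained with a region-weighted loss
`L = BCE(p·M_occder, t·M_occder) + λ₂·BCE(p·~M_occder, t·~M_occder)`
(λ₂ = 5). For an instance pair, cross-prediction of both amodal masks and
comparison of the relative area growths `Δ = (|Ma| − |M|)/|M|` decides the
relation: both ≈ 0 → no occlusion; the instance that grows more is the
occluded one.

**Evaluation** (`amodalgrape.mask_core`): IoU, boundary IoU (inner bands
within distance d of the background, d = 2% of the instance diagonal by
default), and amodal IoU against the true complete mask.

**Fixtures** (`amodalgrape.fixtures`): procedural grape-like instances and
depth-ordered scenes with exact amodal ground truth, so everything above
is testable with no dataset download. The networks run on a compact
numpy autodiff engine (`amodalgrape.nn`) — no deep-learning framework
required.

## Worked example

```python
import numpy as np
from amodalgrape import synthesize_pair, amodal_iou, boundary_iou
from amodalgrape.fixtures import pool_from_fixtures

pool = pool_from_fixtures(12, rng_seed=42, scale=36)
sample = synthesize_pair(pool, rng_seed=7)
print(f"case alpha={sample.case_alpha} beta={sample.beta:.3f} "
      f"gamma={sample.gamma} epsilon={sample.epsilon:.3f}")
print(f"canvas {sample.m_intact.shape}, intact {sample.m_intact.sum()} px, "
      f"visible {sample.m_occ.sum()} px")
iou = amodal_iou(sample.m_intact, sample.m_occ)
print(f"amodal IoU of the visible mask (before completion): {iou.value:.4f}")
b = boundary_iou(sample.m_intact, sample.m_occ, "auto")
print(f"boundary IoU at d={b.d:.0f}: {b.value:.4f}")
```

prints

```
case alpha=8 beta=0.446 gamma=False epsilon=0.116
canvas (75, 63), intact 1431 px, visible 1265 px
amodal IoU of the visible mask (before completion): 0.8840
boundary IoU at d=1: 0.7289
```

The occluder approached from the bottom-right sector (case 8) with an
overlap ratio of 0.446, hiding 11.6% of the occluded instance. The visible
mask already reaches amodal IoU 0.88 against the complete mask — that gap
is what the completer closes — while the boundary IoU of 0.73 shows the
damage is concentrated on the contour. Training a completer on such
samples and evaluating held-out pairs is three lines:

```python
from amodalgrape.experiments import train_scaled_completer, evaluate_completer

model = train_scaled_completer("overlap", seed=0)     # ~1 min, CPU
print(evaluate_completer(model, seed=0, n_pairs=100))
```

The same flows are available from the shell via the `amodalgrape` CLI
(`make-fixtures`, `synthesize`, `extract-supervision`, `train-amodal`,
`train-heads`, `predict`, `evaluate`).

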