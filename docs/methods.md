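# Methods

`amodalgrape` implements a de-occlusion pipeline for cluster-fruit imagery:
instance segmentation heads that are explicitly supervised on the pixels a
mask size-transformation corrupts, an occlusion-synthesis engine that
manufactures (occluded, occluder, intact) training triples, a U-Net mask
completer trained on those triples, and a cross-prediction rule that infers
which of two overlapping instances is in front. This note records the
models, the conventions, and the design choices made where the design was
genuinely open.

## Mask primitives and metrics

Masks are 2-D boolean arrays, 0-based, y down; boxes are half-open
`[x0, x1) x [y0, y1)`. Bilinear resizing follows the half-pixel-center
convention (`x_in = (x_out + 0.5) * n_in/n_out - 0.5`, edge-clamped) and is
implemented as a separable weight-matrix product so its semantics are fixed
by this package, not by a library's resampler. Interpolated masks binarize
at 0.5 with ties counted as foreground (implemented with a `0.5 - 1e-9`
threshold so the rule is stable under reordered float summation).

Three agreement metrics are provided, all in [0, 1], all defined as 1.0 for
two empty masks and 0.0 for empty-versus-nonempty:

* **IoU** — `|A∩B| / |A∪B|`.
* **Boundary IoU** — IoU restricted to the *inner* boundary bands
  `X ∩ X_d`, where `X_d` is the set of pixels whose Euclidean distance to
  the background is at most `d`; the image border counts as background.
  `d="auto"` uses 2% of the ground-truth mask's bounding-box diagonal,
  floored at 1 px. Euclidean distance (not Chebyshev) was chosen for
  rotation robustness; inner bands follow the `G_d ∩ G` convention.
* **Amodal IoU** — plain IoU between a completed (amodal) prediction and
  the true full extent of an occluded instance; numerically identical to
  IoU but kept as a named metric because it is the pipeline's headline
  score.

A 3×3 eight-connected Laplacian boundary extractor provides the thin
boundary masks used by the boundary-supervised baseline head.

## Incoherent-region supervision

When an annotation mask `m` is downsampled (`D`) for training and
upsampled (`U`) back, pixels near boundaries change value. The incoherent
mask is `M_inc = D(m ⊕ U(D(m)))` with `⊕` exclusive-or. Convention: the
`D`/`U` applied to masks binarize at 0.5, but the *final* `D` of the thin
difference ribbon marks every output pixel that received any nonzero lost
coverage. A majority threshold there would erase almost the whole ribbon
on realistic shapes (measured: a 66-pixel ribbon on a 96-px cluster
collapsed to 2 pixels at a 0.6 downsample), leaving nothing to supervise;
the any-coverage rule keeps the construction a faithful "value was lost
here" map. The scene-level incoherent mask is the union of per-instance
incoherent masks — a seam between abutting instances is a boundary of each
instance even though it is interior to their union.

The *local* incoherent mask restricts `M_inc` to instance-meeting points:
for each on-pixel, three pixel pairs are sampled symmetric about the point
at offset `r` (default 2, the 2× downsampling stride) along the
horizontal, vertical, and main-diagonal directions. A pair straddles two
instances iff both members are in-bounds and carry two distinct *nonzero*
ids — instance-versus-background pairs do not count, since the construct
exists to isolate instance-overlap seams. A point is kept iff at least two
of its three pairs straddle.

Per-proposal supervision triples are built in six steps: scene incoherent
mask at the train-time downsample (default 60% of the source frame, the
typical input scaling for proximal cluster images), local restriction
against the label map, upsample of the local mask to the image frame, crop
of both the local mask and the instance mask by the proposal, resize of
the instance crop to the mask-decoder size (28) and its own incoherent
transform to the incoherent-decoder size (56 by default), and a final
logical AND that guarantees the local target is a subset of the instance
incoherent target. Two degenerate cases are handled explicitly: proposals
that miss the instance yield an all-zero triple with a `degenerate` flag
and a warning; crops smaller than the decoder output (where the transform
would be an identity) are first brought to twice the output size so the
transform is a genuine 2× downsample. Whether the local crop should go
through the incoherent transform again rather than a plain resize is an
open reading; the plain resize is the default (an "incoherent region of an
incoherent region" is degenerate) and the alternative is available behind
`apply_eq2_to_local=True`.

## Occlusion synthesis

Complete instances live in an instance pool (tight-cropped RGB + mask;
foreground pixels are kept strictly nonzero so the grayscale→boolean
round trip the compositor uses cannot punch holes). The overlapping-cover
strategy draws an occluded and an occluder instance and composes them
under a directional case `α ∈ 1..8` (45° sectors):

* **Corner cases (α even)** follow the printed top-right layout: overlap
  extents `wβ = round(β·w_occ)`, `hβ = round(β·h_occ)`, canvas
  `hs = h_occ + h_occder − hβ`, `ws = w_occ + w_occder − wβ`, with the
  other three corners obtained by reflecting the layout about the canvas
  axes.
* **Cardinal cases (α odd)** overlap along a single axis to depth β; the
  transverse placement is centred with uniform ±10% jitter of the
  transverse extent. This geometry is an extrapolation — only the corner
  layout is fully pinned down — and is documented as such.

Filters: occluders are rejection-sampled until the height filter
`0.9·h_occder < h_occ < 1.2·h_occder` passes; after composition the
occlusion rate `ε = 1 − |visible| / |intact|` must exceed 0.1, otherwise β
is raised by 0.05 (capped at 0.85) and, failing that, the pair is
resampled — the printed retry loop alone can diverge, so the cap plus
resampling guarantees termination. β is drawn uniformly from (0.2, 0.85].

*Reverse synthesis* (`γ`, Bernoulli(0.5) per sample by default): the
untouched occluder becomes both input and target — an identity mapping
that regularizes the completer against inflating instances that are
actually in front. In both modes the emitted masks satisfy
`m_occ = m_intact AND NOT m_occder` exactly.

The random-cover baseline pastes the occluder at a uniform offset subject
only to bounding-box intersection — no filters, no directionality.

Samples are letterbox-padded to square and resized to the network input;
after resizing, the visible mask is re-derived from the resized intact and
occluder masks so the mask algebra survives resampling.

## Dual-decoder heads and PALM

The heads consume ROI features at 14×14 (mask stream) and 28×28
(incoherent stream). Each stream is refined by two cascaded 3×3
convolutions (the cascade depth is configurable; two is the default
reading of "multiple"), the mask stream is deconvolved to 28 to align the
resolutions, a pixel affinity learning module couples the streams, a
stride-2 convolution brings both to 14, a second (independently
parameterized) PALM couples them again, and deconvolutions produce the
outputs: 28×28 mask probabilities and 28 or 56 px incoherent
probabilities, both through a 1×1 convolution and a sigmoid.

PALM: concatenate the two c-channel inputs, compress 2c→c→2c through two
3×3 convolution blocks with ReLU, split back into two grids, apply a
two-way softmax across the branches per position and channel (computed as
`σ(F1−F2)`, `σ(F2−F1)`, which sum to one exactly), reweight the inputs,
reduce the reweighted concatenation to c channels, and add a
squeeze-and-excitation transform (reduction ratio 4) of that shared
representation back to each input.

Losses: the mask decoder uses mean BCE with probabilities clamped to
`[1e−7, 1−1e−7]`. The incoherent decoder uses dice+BCE against the
instance incoherent target plus `λ` (default 2) times dice+BCE of the
prediction restricted (elementwise product) to the local incoherent
target; dice uses the `+1` smoothing in numerator and denominator. The
boundary-supervised baseline replaces the incoherent targets with
Laplacian boundary masks, leaving every tensor contract unchanged.

The backbone, RPN and box head of a full two-stage detector are out of
scope: the training harness encodes ground-truth-jittered proposal crops
with a small shared convolutional encoder, which is exactly the pluggable
feature-provider role ROI Align plays in the full model.

## Mask completion and the occlusion relation

The completer is a U-Net over two binary mask channels (visible occluded
mask, occluder mask): depth-4 encoder/decoder with two 3×3 convolutions
per level, stride-2 convolutions for downsampling, kernel-2 stride-2
transposed convolutions plus skip concatenation for upsampling, base width
32, sigmoid output at input resolution. The completion loss is BCE
restricted to the occluder region plus `λ2` (default 5) times BCE on its
complement: the complement term anchors the prediction to the visible
input while the occluder term drives hallucination of the hidden part.
Full-scale defaults follow the stated training recipe (320 px input, Adam
with lr 1e−4, β₁ 0.9, weight decay 5e−4 folded into the gradient, batch
16, 15000 iterations, warm-up plus cosine annealing); every value is
overridable.

For two segmented instances with intersecting boxes, the relation rule
cross-predicts `f(M_i, M_j) → Ma_i` and `f(M_j, M_i) → Ma_j` and compares
the relative growths `Δ = (|Ma| − |M|)/|M|`: both at or below τ means no
occlusion (−1); otherwise the instance that grew more is the occluded one
(1 when the first grew more, 0 for the reverse). τ = 0.01 because an exact
zero branch is measure-zero for a real network; an exact tie above τ —
not covered by the three-branch table — is reported as 0 with an
`ambiguous` flag. The completer consumes binarized masks (threshold 0.5),
not probabilities.

## Numerical engine

The networks run on a small reverse-mode autodiff engine written for this
package (NCHW tensors, im2col convolutions, transposed convolutions as the
adjoint of convolution, squeeze-and-excitation, Adam). Gradients are
verified against central finite differences to ~1e−10 in the test suite.
Parameters are float32 for speed; graphs built from float64 inputs (the
public loss functions) stay in double, which is why the loss values match
per-pixel oracles to better than 1e−9. All randomness flows through
seeded `numpy` generators; identical seeds give byte-identical samples and
loss traces.

## Synthetic fixtures

A fixture instance is the largest connected component of 15–40 jittered
circles ("berries", radius ≈ scale/6) whose centres lie in a prolate
ellipse — an irregular, lobed, cluster-like silhouette whose pixel-scale
contour detail is exactly what the incoherent-region construction feeds
on. Scenes place instances with a known depth order (later paints over
earlier), recording exact visible masks, amodal masks and occluder edges;
non-overlapping placements keep a 5-px clearance so "no overlap" also
means "beyond the pair-sampling offset". The generator reproduces the
geometry of cluster occlusion but none of the photometric nuisance of
field imagery (lighting, leaf clutter, blur), so green tests validate the
algorithms' contracts, not field robustness.

## Scaled reference experiments

Full-scale training is GPU-sized; the package's reference experiments
(`amodalgrape.experiments`) run the same code at desk scale: 64 px
letterboxed samples, a depth-3 width-8 U-Net, 400 Adam iterations at
lr 1e−3 (cosine schedule) and batch 4, an instance pool of 40 procedural
clusters, and 100 held-out evaluation pairs from a disjoint 20-cluster
pool — the smallest configuration where the from-scratch completer
converges reliably. The learning rate is raised from the full-scale 1e−4
because the scaled problem is far smaller; the full-scale value remains
the estimator default. The three-way study (overlapping cover with
reverse synthesis, random cover, overlapping cover without) is averaged
over three seeds and asserted as orderings, not absolute values: held-out
amodal IoU after completion must beat the visible-mask baseline,
overlap-trained must match or beat random-trained, and reverse synthesis
must shrink the area growth the completer assigns to occluders.

## Known limitations

* One occluder per occluded instance; multi-occluder scenes are not
  synthesized.
* No photometric blending or lighting harmonization in the compositor.
* The heads harness trains against jittered ground-truth proposals, not a
  learned detector; detection AP is out of scope.
* The cardinal-case paste geometry is an extrapolation of the printed
  corner layout.
* Fixture realism is geometric only; absolute metric values on fixtures do
  not transfer to field imagery, which is why acceptance is stated as
  properties and orderings.
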