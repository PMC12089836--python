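# Methods

## Detection pipeline

The package implements a real-time detection-transformer (DETR-family)
pipeline with two assemblies sharing one decoder:

* **baseline** — ResNet18 backbone (stem + 4 stages of 2 BasicBlocks,
  widths 64/128/256/512), a single post-norm transformer encoder layer with
  plain multi-head self-attention on the stride-32 level (AIFI), and a
  convolutional cross-scale fusion neck (CCFF: top-down FPN + bottom-up PAN
  with CSP/RepVGG blocks, hidden width 256, expansion 0.5, depth 3);
* **improved** — the same topology with the wavelet-convolution backbone,
  M2SA replacing the encoder's attention sublayer, and the CSRFPN neck.

The decoder consumes the flattened multi-scale memory.  Every memory
position predicts a class score and a box (an MLP delta added to a
grid-anchor logit); the top 300 positions by class confidence become the
decoder queries (content = the detached memory feature, reference = the
detached predicted box).  Three decoder layers apply self-attention,
multi-scale deformable cross-attention (8 heads, 4 sampling points per
level, offsets scaled by the reference box size), and a feed-forward block;
each layer refines the reference boxes in logit space and carries its own
auxiliary class/box heads.  No NMS is applied anywhere.

The query-selection scheme scores proposals by classification confidence
restricted to geometrically valid anchors; the uncertainty between
classification and localisation is handled by the matching cost and the
per-layer auxiliary supervision rather than by an explicit selection
penalty.

**Training.**  Hungarian matching (cost weights: class 2, L1 5, GIoU 2 —
solved with `scipy.optimize.linear_sum_assignment`) assigns queries to
ground truth; the loss is sigmoid focal classification (α 0.25, γ 2,
normalised by the ground-truth count) + L1 + GIoU box regression (weights
1 / 5 / 2) over all decoder layers and the encoder proposal head.
Denoising queries stabilise early convergence: ground-truth boxes are
jittered (centre shift and scale noise up to ±40% of the box size),
embedded through a learned class embedding, and decoded alongside the
matching queries with an attention mask that isolates denoising groups
from each other and hides them from the matching queries.  Negative
denoising pairs are not used; the positive-only variant was sufficient at
the problem sizes this package targets and keeps the token budget small.
The optimiser is AdamW (lr 1e-4, weight decay 1e-4, global gradient-norm
clip 0.1), batch size 4 — the reference training configuration; the CLI
defaults to 5 epochs so smoke runs stay desk-scale (the reference schedule
is 300 epochs).

## Wavelet convolution

The 2-D orthonormal Haar transform maps each 2×2 block
[[a, b], [c, d]] to (a+b+c+d)/2 (LL), the column difference (a−b+c−d)/2
(LH), the row difference (a+b−c−d)/2 (HL) and the diagonal (a−b−c+d)/2
(HH); the inverse is its transpose, so reconstruction is exact and energy
is conserved.  Odd-sized maps are reflect-padded to even before analysis
and cropped after synthesis.

WTConv(x) = base_dwconv(x) + IWT-cascade, where the cascade decomposes the
map, applies a depthwise k×k kernel on each subband, recurses on the raw
LL band, and reconstructs.  Defaults: ℓ = 2 levels, band kernel k = 3,
full-resolution depthwise base kernel 5.  Inside the backbone each
replaced 3×3 convolution becomes depthwise-WTConv → BN → 1×1 pointwise
(the pointwise carries any stride), so channel mixing is preserved at a
fraction of the dense cost.

Two accounting conventions coexist deliberately: the formula API
(`flops_wt`, `flops_bands`, `flops_iwt`) implements the printed closed
forms — including the dense C_in×C_out factor in the per-band term — while
the model profiler costs the operator as actually implemented (depthwise
bands + pointwise mix, plus the transform terms).  Both are exposed; the
distinction is documented because the closed form overstates the depthwise
operator's cost.

**Replacement policy.**  Which convolutions to replace is a free design
axis.  The shipped default replaces the *second* 3×3 convolution of every
BasicBlock ("second"); replacing both ("both") makes the backbone several
times lighter than the architecture profile this package reproduces, so it
is available as a config option but not the default.  At reduced input
sizes the deepest stage's maps become too small to decompose twice; the
backbone's WTConv instances therefore truncate the cascade so the smallest
decomposed map stays ≥ 2×2 (the functional operator keeps the strict
error instead).

## M2SA encoder block

For input X ∈ R^{C×H×W} (C = 256, 8 heads):

* multi-scale branch: 1×1 reduction to C/4, three parallel depthwise 3×3
  atrous convolutions at rates {1, 3, 5} (receptive spans 3/7/11), summed,
  1×1 restoration to C, and the result gates X by elementwise product.
  The published description can be read as applying the gate twice; the
  default applies it once (matching the semantics of the block it derives
  from), and `literal_double_gate=True` implements the literal double
  product.
* attention branch: queries from X, keys/values from the gated feature
  (optionally pooled by `kv_downsample`; default 1, since the stride-32 map
  is only 20×20 at 640 px input), multi-head scaled dot-product attention
  with an output projection.  The 2-D sine-cosine positional embedding is
  added to the tokens entering Q and K only.
* channel branch: global average pool → 1×1 to C/16 → ReLU6 → 1×1 → sigmoid,
  broadcast-multiplied with X (SE reduction 16, the standard default).

The branch outputs are summed; with every learned weight zero the block
reduces exactly to 0.5·X (zero multi-scale gate, zero value projection,
sigmoid(0) channel gate), which the tests assert.  The encoder layer keeps
the usual residual + LayerNorm + FFN structure (FFN width 1024) and is
applied to the stride-32 level only; constructing it for another level is
a configuration error.

## CSRFPN neck

* **RCM**: horizontal and vertical average pooling broadcast-added into a
  rectangular map, refined by depthwise strip convolutions 1×k then k×1
  (k = 11) with BN+ReLU between and a sigmoid after; the attention gates a
  depthwise 3×3 transform of the input.  Strip convolutions use
  edge-replication padding so a constant map yields a spatially uniform
  attention (zero padding would leak border artefacts into the gate).
* **PCE**: average-pool P3/P4/P5 by 8/4/2 to the shared H/64 grid,
  concatenate, fuse 1×1 to width 256, refine with a stack of 2 RCMs.
* **DIF**: bilinear-resize the low-resolution input to the target grid,
  1×1 channel match, elementwise add.
* **MFF**: gate = h_sigmoid(conv(X_low)) with h_sigmoid(t) = clamp(t+3,0,6)/6,
  bilinearly resized and multiplied onto conv(X_high).  The conv kernels
  are configurable; the shipped default uses a 3×3 on the high-resolution
  input of the stride-16 fusion and 1×1 at stride-8, with 3×3 gate convs —
  the combination whose neck cost matches the architecture profile the
  package reproduces.

Wiring: context = PCE(P3,P4,P5); N5 = RCM(DIF(P5, context));
N4 = RCM(MFF(P4, N5)); N3 = RCM(MFF(P3, N4)).  All bilinear resampling uses
half-pixel-centre alignment (corners not aligned) for reproducibility.

## Synthetic data generator

The generator emulates the study conditions the package targets: 640-px
(configurable) RGB images of a green leaf canopy (low-frequency mottling +
pixel grain), carrying 1–12 objects of two classes — irregular brown
blight lesions covering ≥ 2% of the image area (regenerated if edge
clipping shrinks them below that) and small elongated dark mirid bugs
≤ 1% — with at least half of multi-object images containing a deliberately
overlapping pair.  Augmentation expands each source image into 8 variants
(original, horizontal/vertical flip, three right-angle rotations, Gaussian
noise σ = 10 on the uint8 scale, flip+noise); right angles keep the box
transforms exact, and an arbitrary-angle rotation with box re-fitting is
available behind a flag but excluded from the exactness invariants.
The split is grouped by source image (70/20/10 by default — the published
counts 896/256/128 out of 1280, which the stated 7:1:2 ratio contradicts;
the counts win).

What the generator does *not* model: photorealistic leaf venation,
specular lighting, motion blur, annotation noise, class imbalance drift,
or scale statistics of real field photos.  Tests passing on these fixtures
certify the pipeline's correctness (geometry, losses, matching, metrics,
determinism), not field accuracy; the accuracy tables of the original
field study are out of reach without its (undeposited) photographs and
GPU-scale training.

## Metrics and profiler

Greedy score-ranked matching per class at an IoU threshold feeds PR
curves; AP uses the 101-point interpolated envelope (the continuous
area-under-curve definition does not name a convention; 101-point is the
COCO-style standard and agrees with exact envelope integration within 0.01
on randomized rankings, which the tests check).  mAP50:95 averages IoU
thresholds 0.50:0.05:0.95.  Zero denominators return 0 by convention.
FPS = 1/mean(inference time) is reported for information only — it is
hardware-dependent and never asserted.

The profiler runs the real forward graph in a shape-only ("meta") mode:
every matrix-multiply-shaped primitive (conv, linear, attention matmul)
adds 2×MAC (+bias adds) to a counter; normalisation, activations, pooling,
interpolation and the deformable gather count zero, matching common
per-layer profiling tools.  WTConv layers add their transform cost through
the closed forms above.  A second, independent counter prices each layer
from module attributes and hook-recorded shapes; the two agree within 1%
(tested).  The serialized "size" is the float16 checkpoint in bytes
(≈ 2 bytes/parameter).  The convention is stated prominently because
FLOP conventions differ by 2× between tools.

## Problem sizes used by the test suite

Chosen as the package's own desk-scale defaults: gradient checks on ≤ 6×6
maps in float64; dataset-procedure checks generate 160 sources at 96 px;
the end-to-end oracle trains the full variant on 8 images at 64 px for 200
iterations (batch 4, lr 2e-4) and must reach mAP50 ≥ 0.90 on those images;
architecture profiling always runs at the reference 640 px, which is
exact and training-free.

## Known limitations

* Accuracy metrics on real field data are not reproducible here (no public
  dataset); all accuracy-bearing tests use synthetic fixtures.
* Training is CPU-bound and desk-scale; the 300-epoch reference schedule is
  supported but not exercised.
* The deformable-attention sampling is priced at zero FLOPs by convention;
  profilers that count gather/interpolation will report slightly higher
  totals.
* Denoising uses positive pairs only; contrastive (negative) denoising is
  not implemented.
* The Haar family is fixed; other wavelet families and learned filters are
  out of scope.
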