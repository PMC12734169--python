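# Methods

`pestdet` implements a lightweight single-stage detector family for
crop-pest imagery, together with the loss, metric and data machinery needed
to verify every component at desk scale on a single CPU.  This note records
the models, the parameters that matter, the numerical choices, and what the
synthetic data can and cannot show.

## The detector family

The baseline is a nano-scale anchor-free one-stage detector: a convolutional
backbone with split–transform–concat feature blocks (`C3k2`) in the early
stages and area-attention stages (`A2C2f`, pairs of attention blocks with
multi-head self-attention restricted to horizontal strips plus a
convolutional MLP) at strides 16 and 32; a top-down/bottom-up feature
pyramid neck; and a decoupled detect head that predicts, per cell of the
stride-8/16/32 grids, `nc` class logits and four discretised box-side
distances (distribution-focal regression over 16 bins per side).  At nano
scale with five classes the baseline holds 2.52 M trainable parameters and
6.0 GFLOPs at 640×640 under the convention below.

Four orthogonal modifications are studied, each a flag on the graph builder:

* **EMA attention** (`ema`).  Two efficient multi-scale attention blocks at
  the backbone tail (after the stride-32 convolution and after the final
  attention stage).  EMA splits channels into `g = 8` groups; per group a
  1×1 branch built from height- and width-wise average pooling gates the
  features, a 3×3 branch captures local structure, and two cross-spatial
  attention maps are formed by matrix products between each branch's
  softmax-normalised global descriptor and the other branch's spatial map;
  the input is rescaled by the sigmoid of their sum.  Channel count is never
  reduced.  The group count is the one free parameter; `g = 8` keeps 32
  channels per group at the 256-channel tail and reproduces the family's
  published size increment for this insertion (+0.02 M).
* **Fusion rewiring** (`fusion`).  The baseline fuses the mid-scale head
  path at stride 16 (downsample the P3 feature, concatenate with the
  top-down P4 feature, process).  The rewired head advances this fusion to
  stride 8: the P3 head feature is concatenated with the ×4-upsampled
  backbone tail, processed by an attention-free `A2C2f` at stride 8, and
  only then brought to stride 16 by a depthwise-separable downsample that
  feeds the mid-scale detect input.  Spatial detail thus reaches the fusion
  before any further convolution erodes it; the cost is concentrated at the
  stride-8 grid (+0.7 GFLOPs) while parameters drop slightly (−0.01 M)
  because the heavy 3×3 downsample of the baseline path is replaced by a
  depthwise pair.  The published per-variant profile table pins this
  wiring: it is the only candidate in the enumerated design space matching
  the fusion-only and fusion+EMA rows simultaneously.
* **Wise-IoU v3 box loss** (`wiou`).  See below.  No graph change.
* **C3k2-B** (`c3k2b`).  The three `C3k2` sites marked in the architecture
  (the two early backbone stages and the stride-32 head stage) are replaced
  by `C3k2-B`: a 1×1 transition, channel split, a 1×1 convolution per half,
  `n` adaptive residual blocks (ARBlock) on one half, concatenation, and a
  1×1 fusion.  ARBlock: depthwise 3×3 → pointwise 1×1 + batch norm + SiLU →
  three parallel depthwise 3×3 branches at dilations 1/3/5 (receptive
  fields 3, 7, 11 at equal parameter cost) → concatenation → batch norm →
  efficient channel attention (ECA; global pooling, 1-D convolution across
  channels with the adaptive kernel rule k = nearest odd to
  |log2 C + 1| / 2, sigmoid gate) → pointwise projection back to the block
  width → adaptive gate.  The gate is a 1×1 convolution + sigmoid computed
  from the *residual* stream, blending pointwise
  `out = g·conv + (1−g)·residual`, so every output element is a convex
  combination of the transformed and raw features.  Net effect at the three
  sites: −0.10 M parameters.

## FLOP accounting

One multiply-add counts as two FLOPs; batch norm is folded into its
convolution; sigmoid-family elementwise ops (SiLU activations, attention
gates) are costed at 9 FLOPs per element (a polynomial exponential at 6,
plus add, divide, and the product with the gated value); attention matrix
products and softmaxes are excluded, following the module-level accounting
that this detector family's reported tables use.  The profiler and the
executed layers share one accounting method per module, so the reported
numbers cannot drift from the code.  Under this convention the six ablation
profiles reproduce the published table to the printed precision in eleven of
twelve entries; the C3k2-B-only variant computes 5.82 GFLOPs against a
published 5.9 (−1.4%), and an exhaustive search over the block's unspecified
channel arithmetic found no configuration satisfying all twelve printed
values at once — we prefer the structure that matches the textual
description and the full-model profile exactly.

## Wise-IoU v3

For a predicted/true box pair, `L_IoU = 1 − IoU` and
`R_WIoU = exp(d² / D²)` where `d` is the centre distance and `D` the
diagonal of the smallest enclosing box; `D²` is detached so the enclosure
scales the loss but receives no gradient.  `L_WIoUv1 = R_WIoU · L_IoU ∈
[0, e)`.  Version 3 multiplies by the non-monotonic focusing coefficient

    γ(β) = β / (δ · α^(β−δ)),   β = L*_IoU / L̄_IoU,

with α = 1.9, δ = 3 (γ(δ) = 1 exactly; unique maximum at β = 1/ln α ≈ 1.56;
γ → 0 as β → ∞).  β is the detached ratio of the current IoU loss to an
exponential moving average L̄ with momentum m = 0.99 per batch, warm-started
at the first batch's mean and updated with the (assignment-weighted) batch
mean *after* the loss is formed.  Per-anchor β uses per-anchor loss against
the global running mean.  Because L̄ drifts with training, the quality
classification of anchors is relative, not absolute: rescaling the entire
loss stream leaves the β sequence unchanged.  The momentum is the one
parameter the description leaves open; 0.99 changes L̄ by ≈1% per batch,
slow enough that β is stable within an epoch — it is exposed in the
configuration.

## Training

Task-aligned assignment (top-10 anchors per target by
`score^0.5 · IoU^6` among anchors whose centre lies inside the target box;
collisions resolved by the larger metric; class targets are the normalised
metric), BCE classification, distribution-focal regression on the two
neighbouring bins, and the selected IoU-family box loss, with gains
7.5/0.5/1.5 (box/cls/dfl), all normalised by the summed target scores.  SGD
with momentum 0.937, weight decay 5·10⁻⁴ on convolution kernels only,
initial rate 0.01, three warmup epochs (linear from 10%) then cosine decay
to 1%.  These defaults follow the published configuration (100 epochs,
640×640, batch 8) and are what `TrainConfig()` constructs.

### Desk-scale smoke protocol

Full training on the real imagery needs GPU-days; the repository instead
verifies *learnability* end to end: the fully improved variant is trained on
60 seeded synthetic scenes at 160×160 for 30 epochs (batch 8) and must (a)
reduce its training loss, with the 5-epoch smoothed curve non-increasing,
(b) exceed 0.5 mAP50 when evaluated on its own training split, and (c) keep
the Wise-IoU outlier degree centred near 1 at convergence (the running-mean
fixed point).  The protocol size was chosen so the whole run takes a few
minutes on one CPU.  The learning rate for this short schedule is raised to
0.02: 210 optimisation steps is two orders of magnitude fewer than the
published schedule, and the published rate of 0.01 (tuned for ~125k steps)
leaves the run visibly underfitted, while 0.04 destabilises the classifier.
This is a parameter of the shortened protocol, not of the model;
`TrainConfig` keeps 0.01 as its default.

## Synthetic scenes

Scenes emulate the *statistics* that matter to the method, not photometry:
a smooth leaf-green texture; Poisson(3.5) targets per image; five archetypes
— clustered dark ellipses (aphids), serpentine bright trails whose label box
is the trail extent and therefore mostly background (leafminers; these
exercise exactly the low-quality-box regime the focusing loss targets),
textured pale and red blobs (moths, red-melon beetles), and clustered bright
ellipses with 1–3% image-area label boxes (whiteflies).  Flip augmentation
doubles the training split only (independent horizontal/vertical flips at
probability ½; a double-identity draw is forced to a horizontal flip so no
exact duplicate is emitted), and splits are stratified 8:1:1 per class
*before* augmentation — the leakage guard.  What passing the smoke test
shows: the assembled network, assignment, losses and metrics optimise and
rank correctly.  What it does not show: robustness to real foliage clutter,
lighting, motion blur, or genuine inter-class appearance ambiguity.

## Numerical choices and degenerate inputs

Boxes are centre-format floats; geometry is continuous; the IoU test oracle
rasterises on a separable 20 000-cell grid.  Zero-area unions define IoU 0.
Precision/recall with empty denominators are 0 by convention.  AP uses the
101-point monotone-envelope interpolation, so mAP50-95 follows the COCO
threshold family 0.50:0.05:0.95.  NMS is per-class greedy with defaults
conf 0.25 / IoU 0.45, ties broken by box index.  Batch norm uses ε = 10⁻³,
momentum 0.03; convolutions carry biases only where no norm follows.  All
randomness flows from explicit `numpy` generators; a training run is
bit-reproducible for a fixed (seed, config, data) triple on one device.

## Known limitations

The network runs on a hand-written numpy autodiff; it is single-threaded
and two to three orders of magnitude slower than a GPU framework, so the
published 100-epoch/640×640 regime is out of reach by design.  The
acceptance surface is therefore architecture profiles, analytic loss and
metric identities, and the smoke protocol.  Real-data detection quality is
deliberately out of scope.
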