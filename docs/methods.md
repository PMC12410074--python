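# Methods

## Detector family

All four variants share the nano-width scaling (channels 16/32/64/128/256,
stage depths 1/2/2/1) and the decoupled anchor-free head: per level
(strides 8/16/32) a box branch predicts 4×16 distribution-bin logits whose
softmax expectation, scaled by the stride around cell centres at
(i + ½)·s, gives left/top/right/bottom offsets, and a class branch predicts
per-class logits.  The head, decoding and loss are identical across
variants; only backbone blocks and neck change.

**Fusion block** (backbone C2f replacement).  1×1 conv to a hidden width
equal to the input width, exact 50/50 channel split, the processed half
through `n_units` sequential repeats of (star unit → gated attention unit),
concatenation with the untouched half, 1×1 fuse conv.  The star unit is
depthwise 3×3 (+BN) → two pointwise projections to `expansion·C` channels →
ReLU6-bounded branch multiplied elementwise with the linear branch →
pointwise back-projection → residual add.  The gated unit multiplies a
pointwise value branch with `sigmoid(dw3×3(pw(x)))` and adds the projected
product residually.  Ordering (star before gate), the 3×3 depthwise kernel
inside the star unit, and sequential rather than parallel composition are
conventions chosen here; the residual form makes "all weights zero ⇒
identity" exact, which the tests rely on.

**Frequency machinery.**  `blur` is a size-preserving sliding mean that
averages in-bounds samples only (count-exclude boundary), computed with
float64 running sums so that constant fields are reproduced bit-exactly;
hence `extract_high(x) = x − blur(x)` is exactly zero on constants and the
enhancer `x + sigmoid(conv1×1(high)) ⊙ high` is exactly the identity there,
for any weights.  The multiplicative sigmoid gate (rather than plain
additive `conv(high)`) is this package's reading of "modulating the
enhancement intensity".  The multi-scale block pools to fractions
{1.0, 0.5, 0.25} (ceil-rounded), applies 3×3 then 1×1 convs at a branch
width `w`, enhances, resizes back bilinearly (half-pixel-centre
convention), and fuses the raw identity branch (concatenated unconvolved)
plus all scale branches with a 1×1 conv.

**MS-fusion neck.**  Top-down only: 1×1 laterals on P3/P4/P5, a single
multi-scale block on the lateral P5, then each lower level fuses
(upsampled-above, lateral-own) through a pair of multi-scale blocks and a
1×1 merge.  No bottom-up aggregation stage and no extra stride-32 block
after fusion — the simplification that buys the parameter reduction.

## Width calibration

The published complexity budget (3.00 / 2.78 / 2.44 / 2.32 M parameters,
8.1 / 7.4 / 8.2 / 8.0 GFLOPs at 640, nc = 2) is the only quantitative
constraint on the free widths, and the budget rows are not additive: the
full model is ≈ 0.10 M parameters / 0.5 GFLOPs heavier than the baseline
minus the two stand-alone deltas.  The free hyperparameters were therefore
fixed per variant, once, against that budget:

* fusion backbone: `expansion = 3`, `n_units = (1, 1, 2, 1)` per stage;
* neck-only variant: laterals (96, 128, 128), branch widths (32, 16, 16),
  output widths (64, 128, 128);
* full model: laterals (64, 80, 144), branch widths (16, 16, 24), output
  widths (88, 128, 128) — a wider stride-8 output than the neck-only row,
  which is how the published non-additivity is realized here.

Measured values: 3.0008 / 2.7823 / 2.4374 / 2.3197 M and 8.08 / 7.33 /
8.20 / 8.04 GFLOPs; all parameter figures round to the published 2-dp
values and all GFLOPs sit within the documented ±0.2 accounting tolerance
(7.33 prints 7.3 against the published 7.4).

## Complexity accounting

Reported parameter counts cover convolution/affine weights and biases only;
normalization affine vectors are excluded, mirroring the FLOPs convention
(conv/affine layers of the inference-fused graph; normalization,
activations and elementwise ops excluded; GFLOPs = 2·MACs/10⁹).
`count_params` still returns every learnable scalar by default (the
baseline then counts 3,011,222) with `convention="conv_affine"` giving the
reported figure (3,000,822).  MACs are measured by instrumented forward
pass, so pooled/resized branch sizes are whatever the graph actually
executes.

## Synthetic scenes

The generator emulates the survey's imaging conditions rather than its
radiometry: multi-octave value-noise grass (green–brown palette, faint
per-pixel speckle kept below the octave amplitudes so `texture_octaves`
governs the spectrum), burrows as dark ellipses (semi-axis 6–14 px by
default) with a lighter excavated-soil rim, dung as irregular star-convex
brown blobs (4–10 px), both blended at contrast 0.55–0.9, counts Poisson
(rates 4 burrows / 2 dung / 3 distractors per image), centres separated by
rejection sampling with bounded retries (failed placements are skipped,
which depresses realized counts slightly on small canvases).  Stones and
shadows are drawn but never labeled, exercising the background
false-positive channel.  Labels are tight boxes over every visibly blended
pixel, normalized centre format, six decimals.  Everything is a pure
function of (config, seed); images are streamed per-index so datasets of
different sizes share prefixes.  What passing tests do **not** show: real
UAV radiometry, perspective, blur, occlusion or inter-class appearance
overlap — results here bound correctness of the machinery, not field
accuracy.

## Training and evaluation

Momentum SGD (0.937) with weight decay 5·10⁻⁴ on convolution kernels,
linear warmup over 3 epochs to lr0 = 0.01 then cosine decay to lr0·lrf
(lrf = 0.01); documented full-scale recipe 200 epochs, batch 32, 640 px.
Batch norm uses batch statistics with the exact backward (gradients flow
through mean and variance; the frozen-statistics shortcut demonstrably
breaks single-step descent at batch 1).  Targets are assigned by centre
sampling: cells whose centre falls inside a ground-truth box within 2.5
cells of its centre, offsets representable in the 16-bin range, ties to the
smaller box — a deliberate simplification of task-aligned assignment,
adequate for overfitting-style property tests, not tuned for large-scale
accuracy.  Loss = 0.5·BCE + 7.5·(1 − CIoU) + 1.5·DFL, normalized by the
positive-cell count; the DFL term uses a fused log-softmax for conditioning.
Augmentation (horizontal flip + brightness gain) is off by default so
property tests stay deterministic.

Desk-scale problem sizes used by the test suite: trainability is exercised
by overfitting 8 synthetic 128 px scenes for 120 iterations at lr0 = 0.05
(the larger step suits the tiny-set overfit regime; every variant must at
least halve its composite loss), and generator determinism is checked on a
50-image rendering.  Full-scale settings remain available through the same
configs.

Evaluation: greedy score-ordered one-to-one matching at IoU 0.5; 101-point
interpolated AP; mAP50-95 over IoU 0.50:0.05:0.95; scale strata at
32²/96² px² with out-of-stratum truths ignored (detections overlapping them
discarded, not counted as false positives; empty strata report null).  The
six error magnitudes follow the TIDE scheme — foreground IoU 0.5,
background IoU 0.1, each false positive attributed to exactly one category,
magnitude = mAP50 gain after an oracle fix of that category alone, in
points.  Fixes: relabel (cls), snap box to truth (loc), both (both), drop
(dupe, bkg), remove unmatched truths (miss; classes left without truths
drop out of the average).  The cls/both relabel can in principle create a
residual duplicate; the constructed-case tests avoid this and large-scale
magnitudes are unaffected in practice.  Single-class data forces
E_cls = E_both = 0 structurally.

Grad-CAM: channel weights are spatially averaged gradients of the summed
class logit; the positive channel-weighted activation is bilinearly
upsampled and min-max normalized, with a guarded all-zero output when the
score carries no gradient.

## Numerical choices and limitations

float32 throughout (float64 only inside the blur running sums); logistic
functions via tanh to avoid overflow; bilinear/nearest resampling and
adaptive pooling realized as separable linear maps (exactly transposable in
backward); NMS ties broken by list order after a stable score sort; seeded
`numpy` Generators everywhere — a (spec, seed) pair reproduces parameters
bit-exactly, and (config, seed, data) reproduces training trajectories in
single-threaded runs.  Known limitations: no task-aligned assignment, no
mosaic augmentation, inference is single-image (batch 1) in the decode
path, grouped convolutions other than dense/depthwise are unimplemented,
and the engine is CPU-bound — desk-scale by design.
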