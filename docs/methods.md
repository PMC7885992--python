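# Methods

This note records the models, conventions, numerical choices, and known
limitations of `octplaque`, in the order the pipeline runs.

## Coordinate conventions

All processing stays in the polar (r, θ) acquisition domain.  A frame
is an array `(n_alines, n_radial)`: row i is the A-line at angle
i·360°/n_alines, column r the radial sample.  Indices are 0-based, the
θ axis is circular, and after alignment the radial axis is the
half-open range [0, roi_depth).  Physical scales: 5 µm per radial pixel
(200 px ≙ 1 mm) and 0.2 mm per frame (36 mm/s pullback at 180 fps).
Both are config keys, not hard-coded constants.

## Pre-processing

*Guidewire shadow.*  The per-A-line tissue energy (summed intensity
beyond the catheter dead zone, 5% of the radial extent) is thresholded
at 0.35 × median; the shadow interval is the circular (start, width)
pair maximizing the summed below-threshold excess, found exhaustively
over width ∈ [3, n_alines/4] with prefix sums.  An interval is reported
only if its excess is positive; a uniform frame yields "no guidewire".
Full guidewire trackers in this field use dynamic programming with
hand-tuned cost functions; the threshold-plus-max-sum-interval search
is this package's simpler, documented equivalent and recovers phantom wedges to ±2 A-lines.

*Lumen boundary.*  Clinical systems typically delegate lumen detection
to a dedicated segmentation network; here the boundary is the circular path maximizing
the summed radial intensity gradient under a continuity constraint
|Δindex| ≤ 3 between adjacent A-lines, solved by Viterbi dynamic
programming over θ (anchored at the strongest-gradient A-line).
Guidewire A-lines carry a flat cost and are filled afterwards by
circular linear interpolation.  When the unconstrained per-A-line
argmax already forms a feasible path, the DP provably returns exactly
that path.  Externally computed lumen indices can be passed through
(`lumen_index=`), which is the intended route for real clinical data.

*Alignment and ROI.*  Each A-line is shifted left by its lumen index so
tissue starts at column 0, cropped to roi_depth pixels (200 at full
scale, i.e. 1 mm), zero-padded when the A-line is shorter, and
guidewire A-lines are zeroed.  The shift offsets are retained in a
per-frame context and are exactly invertible; `restore_geometry`
scatters an aligned mask back to raw coordinates.

*Despeckling.*  2-D Gaussian, σ = 1, truncated at 3σ (7×7 taps),
reflect boundaries.  Inputs are finally scaled by the stack maximum so
network inputs live in [0, 1] regardless of acquisition bit depth.

## Step 1 — frame detection

A 3-D CNN sees a 5-frame window centered on the target frame
(boundary frames replicate the end frame).  θ padding is parametric:
each depth slice carries the last A-line of its chronologically
previous frame above and the first A-line of its next frame below (the
pullback ends reuse their own wrap-around A-lines); this padding is
applied once at the input, and the convolutions use zero 'same'
padding internally.  r padding is zero — there is no tissue beyond the
ROI.  The full-scale architecture is five convolutions (kernel 3×5×5
as depth×θ×r, stride 1, batch-norm + ReLU), five 2×2×1 max-pools (θ
and r halved, depth never pooled), then FC-1024 + ReLU + dropout and a
2-way softmax.  Filter counts default to (96, 128, 256, 324, 324) and are
configurable, as is the dropout rate (default 0.5).  The argmax tie is broken toward "other" so a perfectly
ambiguous frame never creates a spurious lesion.

## Cleanup

Binary opening then closing of the frame-label sequence with a flat
structuring element of 5 frames, the sequence zero-padded beyond both
ends (a short run touching the pullback end is removed).  The composite
equals a run-length filter — drop positive runs shorter than 5, fill
gaps shorter than 5 — which the tests verify exhaustively over all 2¹⁴
binary sequences of length 14.

## Step 2 — segmentation

SegNet: a VGG-16-arrangement encoder (13 3×3 convolutions with
batch-norm/ReLU in stages 64·2/128·2/256·3/512·3/512·3, five 2×2
stride-2 max-pools storing argmax indices) and a mirrored decoder
whose max-unpool at stage k consumes the indices of encoder stage
6−k, followed by 13 convolutions and a 1×1 classifier head with
softmax.  Odd spatial sizes use floor pooling; unpooling restores the
exact pre-pool shape with zeros in the dropped row/column.

Losses over the softmax output, on soft (probabilistic) counts of the
calcium class:

* weighted cross-entropy, class weights = median(freq)/freq_c where
  freq_c is the pixel frequency of class c over the frames containing
  c (rarer class ⇒ larger weight);
* Dice, 1 − 2|P∩T|/(|P|+|T|);
* Tversky, 1 − TP/(TP + α·FN + β·FP), defaults α = 0.7, β = 0.3
  (α = β = 0.5 is exactly Dice; the α > β default penalizes missed
  calcium more, favoring recall — the standard choice for lesion
  segmentation under class imbalance).

The public loss functions use a zero smoothing term so the
Tversky–Dice identity is exact; training adds a smoothing constant
(default 1.0) to stabilize early gradients.  Hard (argmax) counts are
used for evaluation, soft counts only inside the losses.

In the two-step regime the training set may contain only frames with
at least one calcium pixel; a violating frame is rejected by index.
The one-step regime (train and segment on all frames) is a switch on
the same code path, used by the comparison harness.  An optional
layer-wise fine-tuning sweep (freeze all, unfreeze one parametric layer
at a time from the last backward, one epoch each at 0.1× LR) is
available for transfer-learning workflows.

## Training

Adam (β₁ = 0.9, β₂ = 0.999), initial learning rate 0.001 dropped by
×0.2 every 5 epochs, at most 50 epochs, early stop after 5 consecutive
epochs without validation-loss improvement, best-validation weights
restored.  All stochasticity (init, shuffling, dropout) derives from
one integer seed; identical seeds give bit-identical training curves.

## CRF refinement

Fully connected CRF with unary −log p and a single position-only
Gaussian smoothness kernel k = exp(−Δr²/2σ_r² − Δθ²/2σ_θ²) under a
Potts compatibility, weight ω; mean-field inference with per-pixel
renormalization each pass.  Defaults σ_r = 1.2, σ_θ = 1.1 px, ω = 0.5,
10 iterations.  The kernel "sizes" are interpreted as standard
deviations in pixels, and only the smoothness kernel is used (no
appearance/bilateral term: the unary term already encodes appearance
through the classifier).  Δθ is a circular distance: the vessel wall is a
cylinder.  The fast path exploits separability with an exact circulant
(θ) × Toeplitz (r) matrix product, entries truncated at 6σ, where the
dropped tails are < 2·10⁻⁸; it agrees with the dense O(N²) reference
implementation to < 10⁻⁶ per pixel, which the tests check on random
problems.  With ω = 0 the refinement is exactly the identity on the
(normalized) input.

## Missing-frame interpolation

A frame strictly inside a lesion interval whose mask is empty while
nonempty masks exist on both sides is replaced by a signed-distance
morph: s = (1−t)·sdt(prev) + t·sdt(next), mask = {s ≤ 0}, t linear in
frame position.  Signed distance is negative inside; identical
neighbors reproduce themselves exactly, and the result is always a
sharp binary mask (the reason this was chosen over probability or mask
averaging).  Frames that already have calcium are never altered.

## Quantification

Per lesion (a cleaned interval of frames): maximum arc angle = max over
frames of (A-lines containing calcium) × 360°/n_alines — a
catheter-centric convention natural in the polar domain (a
lumen-centroid convention would differ for eccentric lumens; known
divergence risk); thickness per positive A-line = radial extent × 5 µm
and depth = leading-edge column × 5 µm (column 0 is the lumen after
alignment), both averaged over all positive A-lines in the lesion;
length = frame count × 0.2 mm.  Calcium score (0–4): +2 if max angle
> 180°, +1 if max per-A-line thickness > 0.5 mm, +1 if length > 5 mm,
strict inequalities.  Metrics use the standard confusion-matrix
definitions; a zero denominator yields NaN, never 0.

Cross-validation splits by pullback, never by frame: ids are shuffled
once into k groups; fold i tests on group i, validates on group
(i+1) mod k, trains on the rest, so each pullback is tested exactly
once.

## The phantom

The generator emulates exactly the image properties the pipeline
exploits: a bright 2-px lumen border at a smoothly varying per-A-line
radius (sinusoid + filtered noise, drifting along the pullback),
tissue decaying as exp(−µ·depth) with µ = 0.01/px, multiplicative
gamma speckle (mean 1, s.d. 0.5), a dark guidewire wedge, and lesions
rendered as tissue attenuated to 0.3× background with a 1-px bright
leading edge — signal-poor with a sharply delineated border.  Output is
quantized to uint16 so fixtures round-trip losslessly; a fixed spec is
byte-reproducible.  A separate `speckle_seed` lets repeat "pullbacks"
share geometry with independent noise, the desk-scale analogue of
repeat catheter pullbacks.

What the phantom does *not* model: coherent speckle statistics,
catheter optics and sheath reflections, log compression, eccentric
side-branches, mixed lipid/calcium tissue, motion artifacts.  Passing
tests therefore demonstrate the pipeline's mechanics and internal
consistency, not clinical-grade accuracy.

## Scaled-down study

The end-to-end study trains on six phantom pullbacks of 60 frames ×
64 A-lines × 64 radial samples (ROI depth 32 px), lesions of 8–18
frames with 13–25 A-line arcs at ~25% frame prevalence: three
pullbacks train, one validates, two are held out.  The detector uses
filter counts [6, 12] with FC-32 and dropout 0.25; the segmenter two
encoder stages [[8, 8], [16, 16]].  Training pullbacks are augmented
with circular θ rotations — an exact invariance, since rotating the
catheter merely relabels θ — and the LR drop period is stretched to 8
epochs (max 25, patience 6) because a phantom epoch has ~two orders of
magnitude fewer minibatch updates than a clinical-scale epoch; with
the full-scale drop period the optimization would freeze long before
convergence.  These problem sizes keep the whole study at roughly ten
minutes on a single CPU.

## Known limitations

* The lumen and guidewire detectors are phantom-grade substitutes; on
  real data the external-lumen bypass should be used.
* The numpy networks are CPU-bound and meant for the scaled-down
  configuration; full-scale (968×448, VGG-16) training would require a
  GPU framework behind the same module interfaces.
* The CRF is 2-D per frame; no inter-frame pairwise terms.
* Mean thickness averages per A-line (not per frame); the angle uses
  the catheter-centric convention.  Both are stated conventions rather
  than validated clinical choices.
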