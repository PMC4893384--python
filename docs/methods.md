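# Methods

This note records the model, its parameters, the numerical choices, and the
limits of what the synthetic validation shows.

## Tracking model

The tracker performs global tracking-by-detection of a rigid, textured
target. The object model is a Generalized Hough Transform R-table over
SIFT keypoints: each enrolled keypoint stores its sub-pixel position,
descriptor, orientation and characteristic scale, plus its distance `d_i`
to the reference center (the bounding-box center of the template frame)
and the angle of the keypoint→center vector *relative to the keypoint's own
orientation*, which makes the stored geometry covariant with in-plane
rotation. Keypoints are enrolled from the full bounding box without
foreground filtering — the box is deliberately slightly larger than the
object so boundary keypoints are captured; background keypoints are
suppressed later by their segmentation weights, not at enrollment.

Per frame, the pipeline is fixed: detect keypoints globally → compute the
segmentation posterior → weight keypoints → match against the model
(nearest-neighbour descriptor matching with Lowe ratio 0.8, one-to-one by
ascending distance) → cast ring votes → locate the center → classify
positives → estimate scale and rotation → adaptation decision → histogram
update with the final pose. Global (whole-frame) detection is what buys
recovery from total failure; nothing in the pipeline depends on the
previous frame's position estimate except the tracked scale `s_{t-1}`,
which sets the ring radii, and the segmentation model's temporal prior.

### Ring voting

Each eligible matched keypoint (weight > 0.5) deposits total mass equal to
its weight, shared uniformly over the integer cells whose distance to the
keypoint lies in `[0.95, 1.05] · d_i · s_{t-1}`. Sharing by cell count
prevents far-from-center keypoints (long ring perimeters) from outweighing
near ones. Rings thinner than one cell are widened to a half-cell band
about their midline so they always rasterize; off-image cells are dropped
*after* the per-cell share is computed, so clipping loses mass rather than
concentrating it. The accumulator (1 px bins) is smoothed with a Gaussian
(σ = 2 px) before the argmax because rings intersect in thin quantized
arcs; ties resolve to the smallest (v, u) lexicographically, making the
argmax deterministic.

A keypoint is classified positive when it was eligible to vote and the
detected center lies within its ring thickness plus a 2 px tolerance.
Scale is then the median ratio of observed to template center distance over
the positives, and rotation the circular median of the angle change of the
keypoint→center vectors; medians tolerate misclassified positives, and the
keypoint→center formulation cancels the detector's orientation estimate
(which is the least reliable SIFT output) from the rotation estimate
entirely. Keypoints closer than 1 px to the center are excluded from the
ratio/angle statistics as numerically unstable. With fewer than two usable
positives the previous scale and rotation are carried and flagged.

### Segmentation model

Each pixel is a two-class hidden Markov chain observed through its HSV
color. Likelihoods are global histograms: chromatic pixels (saturation
> 0.10 and value > 0.15 of full range) populate a 12×12 hue–saturation
histogram, achromatic pixels an 8-bin value histogram, the two sharing one
normalization. Whether the value histogram should combine with the H–S
part multiplicatively or by routing is an open choice; routing was chosen
because it keeps each pixel's likelihood a single histogram lookup and
avoids double-counting the value channel for chromatic pixels.

The transition matrix uses a stay probability of 0.6 for both classes —
mild temporal smoothing; tracking behaviour is not sensitive to this value
in the 0.55–0.8 range. The foreground histogram is initialized and updated
from pixels inside the convex hull of the positive keypoints (a region
with far fewer background pixels than the box); when the hull is degenerate
(< 3 non-collinear points) the detected box is the documented fallback.
The background histogram samples the annulus between 1.25× and 1.75× the
detected box — close enough to be representative, with a margin against
stray object pixels. Both histograms blend per frame with δ = 0.1; δ = 0
is accepted as the frozen-model limit. Keypoint weights average the
posterior over a square patch of half-width max(4 px, 1.5 × detector
scale), clipped at image borders, so the support grows with the feature.

Posterior normalization is exact (the two class numerators are normalized
to sum to one, with the predicted prior used where both likelihoods
vanish); pixels entering the view start at an uninformative 0.5.

### Adaptation and reset

The update/reset state machine activates when the voted center leaves the
positive-keypoint hull. Candidates are the frame keypoints inside the
detected box with weight > 0.5. Center inside the candidate hull with more
than max(5, 10% of model size) candidates → the candidates are enrolled
(distances de-scaled by `s_t`, angles de-rotated by `θ_t`, so the R-table
stays in template units; duplicates within 2 px and descriptor distance
350 are skipped) and keypoints negative for ≥ 5 consecutive frames are
pruned — but never below 50% of the enrollment size, which protects the
model through partial occlusions. Center outside the hull (or hull
degenerate) → reset mode: the model and both histograms freeze, the frame
is reported as no-detection, and each subsequent frame attempts a
whole-image re-detection. Because the recursive posterior is stale during
an absence, re-detection weights use the frozen histograms under a flat 0.5
prior (a pure likelihood ratio). A re-detection is accepted when at least
8 keypoints match positively and the accumulator peak reaches 25% of the
template's self-match peak; on success the posterior restarts at 0.5
everywhere. The candidate threshold, pruning policy and re-acquisition
thresholds are not determined by the tracking formulation itself; the
defaults above are conservative and all configurable.

### 3D initialization

The 2D pose initializes an external 3D pose tracker by pinhole ray
casting: `z = z_ref / s` with `s` the *cumulative* scale relative to the
enrollment frame (where s = 1 at depth `z_ref`) — apparent size scales
inversely with depth under a pinhole model, which fixes the direction of
the scaling; `x = (u − c_x) z / f_x`, `y = (v − c_y) z / f_y`; `θ̂ = θ`
exactly; `φ, ψ` are copied from the previous 3D pose. The external
refinement stage is a pluggable interface with a pass-through default; this
package does not implement level-set or learning-based 3D refinement, nor
instrument articulation.

## Synthetic data

The generator renders a block-textured rigid target over a smooth
tissue-colored background under an exact per-frame similarity transform
(bilinear interpolation), optionally occluded by a second textured rigid
patch ("instrument") or a soft-edged tissue-colored ellipse ("blob"), with
seeded additive Gaussian pixel noise (σ = 2 of 255 by default). Default
palettes are separable in HSV (blue-ish target on reddish background, the
rigid occluder near-achromatic so it lands in the value histogram); a
camouflage variant overlaps the palettes for stress tests. The target
texture guarantees well over 30 detectable keypoints at enrollment.
Ground truth per frame is the continuous pose plus a visibility fraction
computed against an unclipped rendering with the same sub-pixel phase, so
a fully visible unoccluded target scores exactly 1.0 and evaluation
tolerances only need to absorb ≤ 0.5 px rasterization error.

Four presets mirror the canonical challenge regimes: `instrument_occlusion`
(rigid occluder sweep, 150 frames), `tissue_occlusion` (blob sweep, 150),
`out_of_view` (complete exit, 30 frames fully absent, re-entry; 120), and
`long_term` (2000 frames of slow simultaneous drift in u, v, θ, s).

What the synthetic frames do *not* emulate: specular highlights, smoke,
motion blur, articulation, deformation, illumination change, rolling
shutter. Passing tests therefore demonstrate the geometric and
probabilistic machinery — rotation/scale-invariant center detection,
occlusion state handling, segmentation dynamics — not photometric
robustness on real endoscopic footage.

## Evaluation

Center location error is Euclidean distance in pixels. Precision curves
use a 0–50 px grid in 1 px steps (configurable; any monotone grid preserves
comparisons) and AUC is the mean precision over the grid. Missed
detections are scored either as infinite error over the whole sequence or
by restricting to frames where all compared trackers detect. Box
statistics use 25/75% quartiles with 1.5·IQR whisker fences.

## Problem sizes and tolerances in the checks

The automated checks run tracking on 320×240 frames with an 80×80 target:
500 frames for translation (mean error ≤ 3 px, no misses), a 36-frame
0–350° rotation sweep (≤ 3 px per frame, circular-median θ error ≤ 5°), a
200-frame 1.0→1.5 geometric scale ramp (per-frame relative scale error
≤ 5%), and the out-of-view preset (no-detection on ≥ 80% of absent frames,
re-acquisition within 5 frames of full reappearance at ≤ 5 px). Voting is
verified cell-for-cell against an exhaustive brute-force accumulator and,
for degenerate rings without rotation, against the classic single-vector
voting scheme within one bin; the pixel filter against an independent
scalar forward filter to 1e-9; histogram blending against its algebraic
fixed point to 1e-12; the pinhole bridge by round-tripping to 1e-6 px; and
the whole tracker for byte-identical repeat runs. Measured values land far
inside these bounds (typical center error ≈ 0.4 px, scale error ≈ 0.3%,
θ error ≈ 0.02°).

## Known limitations

- In-plane rotation and scale only; strong out-of-plane rotation appears
  as appearance change and eventually triggers reset rather than pose
  adaptation.
- The segmentation model is purely per-pixel (no spatial regularization),
  and a camouflaged target degrades vote weighting.
- One model per tracker instance; a second instrument is treated as
  background/occluder, not tracked.
- SIFT detection dominates runtime (~0.1 s per 320×240 frame on one CPU);
  the initial-upsampling octave is skipped, which sacrifices keypoints
  smaller than ~2 px that are irrelevant at instrument scale.
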