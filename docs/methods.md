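# Methods

This note documents the models, estimators and numerical choices behind
`axonseg`, the parameters that matter, and what the synthetic test-bench
does and does not establish about real TEM data.

## Problem setting

Unmyelinated axons appear in TEM nerve cross-sections (~12 nm/pixel) as
low-contrast blobs, frequently clumped with only a thin plasma-membrane
gap between neighbors. The quantity of interest is *per-instance*
segmentation: a per-pixel score can be excellent while every touching
pair of fibers is merged, which destroys downstream counts and spatial
statistics. The pipeline therefore (a) trains with an explicit *border*
class, (b) evaluates with instance-matched scores (SQ/RQ/PQ), and
(c) validates the spatial pattern of the detected centroids with
second-order statistics.

## Synthetic image generator (`imgen`)

The generator replaces the microscope for testing. Fibers are filled
superellipses (exponent 1.8–3.5, axis ratio up to the configured
elongation) with a smooth radial intensity gradient and a 1–2 px rim of
opposite polarity, mimicking the membrane contour whose ambiguity the
border class addresses. Placement is dart-throwing with at most 100
retries per fiber; a configurable fraction of fibers is packed into
islands whose members keep 1–3 px background gaps (the clumped-fiber
failure mode). Distractors — myelinated-like rings, nucleus-like
textured blobs, vesicle clusters — are painted into the intensity image
only and never labeled. Background is correlated Gaussian texture;
optional artifacts add a vertical mosaic-seam intensity step. All
randomness flows from one seed; identical configs give bit-identical
rasters.

Default conditions: 512×512 px at 11.9 nm/px, 40 fibers with semi-major
radius 5–18 px, elongation ≤ 2.5, clump fraction 0.3, 5 distractors,
noise sd 6. The radii are a deliberate desk-scale reduction (~3× smaller
than the 0.5–1.5 µm fibers of real data at this resolution) so that
dense multi-fiber fields fit in small rasters; consequences for
post-processing are noted below.

**What passing tests do not show:** the generator does not reproduce
real TEM texture statistics, fascicle architecture, staining gradients,
or stitching misalignment; results on it bound algorithmic correctness
(labels, voting, matching, statistics), not biological segmentation
accuracy.

## Training representation (`labels`)

* **Class maps.** Border = outward 8-connected dilation of each fiber
  support by `border_width` (default 2 px: membrane contours of
  0.01–0.03 µm at ~12 nm/px span 1–3 px), clipped at image edges and at
  other fibers' interiors. Background/fiber/border always partition the
  raster.
* **Shape scores.** Circularity C = 4πA/P² with the 4-direction Crofton
  perimeter estimator. Crofton is asymptotically exact for disks
  (C ≈ 0.995 at r = 30 px), which anchors the score for round fibers; it
  underestimates the perimeter of axis-aligned rectangles, biasing their
  C high by up to ~0.12. The bias is monotone-preserving: C still
  decreases strictly with aspect ratio at fixed area, which is all the
  sampling score s = A·C consumes.
* **Tile sampling.** `random` (uniform windows), `fiber_centered`
  (uniform over instances), `proportional` (area-proportional per-image
  allocation, exposed as `proportional_allocation`, then
  instance-centered within an image), and `area_based` (multinomial over
  instances with probabilities s_i/Σs_j; repeated draws are flagged for
  augmentation). Windows are clamped inside the image, never
  zero-padded. Per-image tile caps are configuration, not constants.
* **Augmentation.** Center jitter re-centers a tile 10 times on uniform
  pixels of its source instance and is restricted to instances whose
  bounding box exceeds the tile; flips emit the 4 variants.
* **Equalization.** Plain 8-bit CDF mapping v → round(cdf(v)·255).
  Constant tiles are returned unchanged: their CDF inverse is undefined
  and equalizing them would inject contrast. The map depends only on
  intensity ranks, so it is invariant to affine rescaling up to
  quantization and idempotent up to one bin.
* **Class weights** are inverse frequencies over the training tiles,
  normalized to mean 1; the border class, having the smallest footprint,
  always receives the largest weight.

## Network and losses (`network`)

A classic U-Net operating on 1-channel equalized tiles: `depth` encoder
stages of two 3×3 convolutions (batch normalization before each ReLU)
and 2×2 max-pooling; a bottleneck with dropout (default rate 0.5)
between its convolutions; a decoder of 2×2 transposed convolutions with
skip concatenations; a 1×1 convolution and per-pixel softmax over three
classes. Channels double per stage from `base_filters` (64 at full
scale; 8–16 in test profiles so CPU runs take minutes). `same` padding
requires the tile side divisible by 2^depth; `valid` padding follows the
unpadded arithmetic (e.g. a 524-px tile yields a 340-px output at
depth 4), with skip features center-cropped.

The implementation is pure numpy — im2col convolutions, hand-written
backward passes — and every loss gradient is verified against finite
differences in the test suite. Determinism is promised per device with
fixed seeds; cross-device bitwise equality is not contracted.

Losses (all return value and gradient):

* **Weighted cross-entropy** (default): mean over pixels of
  w_t · (−log p_t). The two-class "no border" ablation is the same
  computation on two channels with border merged into fiber.
* **Generalized Dice**: 1 − Σ_c w_c Dice_c / Σ_c w_c with w_c the
  inverse class frequency of the target, smoothing ε = 1e-8, and absent
  classes at weight 0 (their inverse frequency is undefined).
* **Focal**: mean of (1 − p_c)^γ (−log p_c), γ = 0.25, no explicit class
  weights; identical to unweighted cross-entropy at γ = 0.

Training is SGD with momentum 0.9 (a conventional default; the momentum
value is exposed in `TrainConfig`), batch size 2, learning rate
0.01 · 0.1^epoch over 4 epochs at full scale. Tiles are equalized before
every forward pass; per-iteration loss history and per-epoch checkpoints
(npz weights + JSON spec sidecar) are recorded; a non-finite loss aborts
with a diagnostic.

## Inference and post-processing (`infer`)

Tile origins advance by the stride with the final row/column clamped to
the image edge, so coverage is exact; with defaults t = 512, s = 64 an
interior pixel is covered by 64 tiles. Voting is over hard per-tile
argmax labels (not averaged probabilities); ties break toward
border > fiber > background, preserving instance separation at fiber
junctions. Edge pixels vote among their available covering tiles.

Post-processing: (1) border pixels → background (keeping them as fiber
merges touching fibers); (2) 8-connected components; (3) components
smaller than `min_instance_px` removed — strictly, so an area of exactly
50 px survives the default; (4) up to `max_dilation` rounds of
simultaneous 1-px dilation, reverting the round's growth for every
instance that would overlap or become 8-adjacent to another. Offenders
are found at the full simultaneous-growth state and reverted at once;
a reverted mask is a subset of its grown mask, so it cannot touch any
accepted growth (which would itself have offended) — one pass per round
suffices, the result is order-independent, and no two final instances
are ever 8-adjacent. Two instances separated by an even gap therefore
halt one round earlier than a sequential scheme would (a 4-px gap closes
to 2 px, not 1 px). Adjacency is tested against instances only, not
against the former border band.

Full post-processing is intentionally *not* idempotent: re-running it on
its own rasterized output dilates isolated instances further (growth is
capped per run, not globally). The component/size-filter stages are
idempotent, and a second full pass preserves instance count and
non-adjacency; tests pin exactly these properties.

**Desk-scale caveat.** The 5-px reconstruction dilation assumes
detections are cores eroded by a predicted border rim — true at the
real data's fiber radii (tens of pixels) where +5 px is a modest
correction. At the test-bench radii (5–18 px) a trained network predicts
essentially full supports, and +5 px inflates instances past the IoU 0.5
matching threshold (even a perfect class map would fail). The dilation
factor is image-dependent by design; the end-to-end desk profile
therefore runs with dilation 0, while the dilation machinery itself is
exercised by dedicated geometry tests.

## Panoptic evaluation (`panoptic`)

Overlaps are accumulated in a single joint (pred, gt) label histogram —
linear in pixels regardless of instance count. Matching requires IoU
strictly greater than 0.5: any two regions overlapping one region at
IoU > 0.5 would need combined area exceeding that region, so partners
are unique and greedy matching equals optimal assignment (tested against
a Hungarian oracle). Ties at exactly 0.5 are excluded; a merged
prediction covering two equal touching fibers scores IoU exactly 0.5
against each and matches neither. SQ is the mean matched IoU, RQ the
instance-level F₁, PQ their product. With no matches at all, SQ (and,
when there are no errors either, RQ) is reported as a NaN sentinel
rather than a silent 0 or 1; scores are printed to 3 decimals.

## Spatial statistics (`spatstats`)

Centroids are pixel-area centers of mass scaled to micrometres. The
K estimator is

K̂(r) = W / (n(n−1)) · Σ_{i≠j} 1{‖x_i − x_j‖ ≤ r} e_ij(r),

with translation edge correction by default (closed form for rectangle
windows, shapely intersection areas for polygons) and Ripley's isotropic
correction available (circle-fraction evaluated numerically on 256 arc
points, valid for polygonal windows; it agrees with translation within
3% on interior-dominated ranges). The centered L-function
L_c(r) = √(K̂/π) − r is zero in expectation under CSR; K is invariant to
intensity and to random thinning, so patterns with different point
counts are comparable.

The kernel intensity estimate is Gaussian with edge correction by
clipped-mass renormalization (each kernel's mass inside the window,
rectangle approximation via normal CDFs); its integral over the window
equals n to quadrature accuracy. The default bandwidth is leave-one-out
likelihood cross-validation over a geometric grid, user-overridable.
The inhomogeneous estimator reweights pairs by 1/(λ̂(x_i)λ̂(x_j)) and
normalizes by D^p·W, D = (1/W)Σ_i 1/λ̂(x_i), p ∈ {1, 2} with default 2,
under which a constant intensity reduces it to the homogeneous K̂ up to
the factor (n−1)/n.

CSR envelopes simulate 39 binomial patterns (fixed n, uniform in the
window) and take pointwise min/max of L_c — a rank-1 envelope with
two-sided pointwise level 2/40 = 5%. Loh's bootstrap treats each point's
local contribution K_i(r) = (W/(n−1)) Σ_{j≠i} e_ij 1{d_ij ≤ r} as a mark,
resamples marks with replacement (degenerate all-one-point resamples are
redrawn), and takes percentile bands of the resulting L_c curves; band
width shrinks as ~n^{-1/2}, and two bands are compared by the fraction
of grid positions where they intersect.

The default r grid spans 0 to ¼ of the window's shorter side (512
points): beyond mid-range distances axon patterns are indistinguishable
from CSR, so the short-to-mid range carries the information.

Numerical conventions: the estimator denominator is n(n−1) (the sign
convention that keeps K̂ positive); pairwise sums are computed once via
a sorted cumulative sum and evaluated on the whole r grid by binary
search.

## Desk-scale end-to-end profile (`pipeline.DeskProfile`)

20 synthetic images, 16 train / 4 held out, cycling the three contrast
modes; 320-px images with 40 fibers (≈11% fiber cover — a realistically
dense field at desk-scale radii); 24 area-based tiles per image at
128 px; depth-2 / 8-filter U-Net; 300 iterations at batch 2 as a single
epoch at constant lr 0.05 with dropout 0 (a per-epoch decay schedule and
heavy bottleneck regularization are calibrated to runs two orders of
magnitude longer); inference at stride 64 with the 50-px size filter and
dilation 0 (above). On one CPU the whole run takes ~3 minutes and scores
SQ ≈ 0.85–0.93, RQ ≈ 0.63–0.92 per held-out image — consistent with the
0.7–0.9 instance-level range reported for real tissue, but established
here only for the synthetic conditions.

## Known limitations

* The numpy network is CPU-sized: full-scale training (512-px tiles,
  64 base filters, 30k iterations) is out of reach; the architecture and
  losses are validated at reduced width/depth.
* Crofton circularity is biased high for axis-aligned near-rectangular
  shapes (bounded in tests at +0.12).
* The isotropic correction is numerical (256 arc points, relative error
  ~0.4%); the translation correction for polygon windows costs O(n²)
  polygon intersections.
* Contour export emits outer boundaries only; interior holes (absent
  from the generator's shapes) would be filled on re-import.
* The expert-in-the-loop cycle is supported as file plumbing
  (XML export, contour re-import, rasterization); the editing workflow
  itself is not modeled.
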