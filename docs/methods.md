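# Methods

## Problem and approach

`gaitspeed` classifies the walking speed of a person — slow (2–3 km/h),
normal (4–5 km/h) or fast (6–7 km/h) — from a lateral-view sequence of
binary silhouettes, without markers or body-worn garments. Because the
apparent size of a body in an image depends on the subject-to-camera
distance, raw pixel measurements (height, widths, areas) are not
comparable across recordings. The method therefore works with five
dimensionless per-frame ratios:

| feature | definition | behaviour over a stride |
|---|---|---|
| HW1 | full-body height / full-body width | dips twice per gait cycle (limbs spread) |
| HW2 | full-body height / mid-body width | dips twice per cycle (arm swing) |
| HW3 | full-body height / lower-body width | dips twice per cycle (leg spread) |
| A1 | apparent-body area / full-body area | silhouette density inside its box |
| A2 | between-legs area / full-body area | opens twice per cycle, 0 at leg crossing |

Under uniform image scaling every numerator and denominator scales by
the same factor, so the ratios are invariant to camera distance. Each
ratio traced over the frames of a walk is quasi-periodic; the five
normalized traces, truncated to a fixed length T, form a 5×T
*walking-speed pattern* that a bidirectional LSTM classifies into the
three speed classes.

## Per-frame measurements

All image operations treat the mask as 0-based, row 0 at the top.

* **Full-body box** — tight axis-aligned bounding box of all foreground
  pixels; its height and width are the full-body height/width, and their
  product is the full-body area. The apparent-body area is the raw
  foreground pixel count.
* **Bands** — the box's vertical extent is split into n near-equal
  contiguous strips with half-open boundaries `floor(i·H/n) ..
  floor((i+1)·H/n)`; the mid-body width is the tight width of foreground
  in the middle third, the lower-body width in the bottom third. An
  empty band marks the frame invalid.
* **Between-legs area** — on the lower half-band of the box: remove
  every 8-connected component whose area is below `noise_fraction`
  (default 0.10) of the largest component (a generalisation of deleting
  the single smallest disconnected object that stays robust with several
  speckles); locate the two toe points (bottom-most pixel of the
  left-most and right-most components, ties broken toward the outer
  column; a single merged component is split at the midpoint of its
  column extent); draw an 8-connected Bresenham line between the toes on
  a working copy; fill background regions not connected to the crop
  border (4-connectivity for background, `scipy.ndimage.binary_fill_holes`);
  the pixel count of `filled & ~pre-fill` is the enclosed area. Closed
  legs (coincident toes, or a gap that reaches the crop border) yield 0.

Frames that cannot be measured — empty frame, empty band, zero
denominator — are dropped from the sequence and logged rather than
imputed; a flat (constant) ratio trace downstream is treated as an
extraction failure and aborts normalization.

Connectivity is 8 for foreground regions and 4 for background fill;
the procedure's region semantics are not sensitive to this choice on
human-shaped masks, but it is fixed for reproducibility.

## Signals and patterns

* **Normalization** — min–max to [0, 1] per signal; constant signals are
  an error, not silently zeroed.
* **Peak counting** — strict interior local maxima; a plateau of equal
  values flanked by strictly smaller neighbours counts once; endpoints
  never count. Over a fixed-length sequence the count is the frequency
  proxy: width- and area-driven signals peak twice per gait cycle.
* **Amplitude** — reported as the relative range `100·(max−min)/max` of
  the raw (pre-normalization) ratio trace. The percentage reading of
  "amplitude" is not uniquely determined by its source; the relative
  range is the simplest scale-free choice and is documented as such.
* **Variation** — the coefficient of variation `100·SD/mean` (sample SD)
  of a raw body-measurement series over consecutive frames; used to
  compare how strongly each measurement oscillates at each speed.
* **Patterns** — the first T valid frames of each ratio series (T = 240
  for long indoor-style sequences, 35 for short outdoor-style ones;
  configurable), each row normalized independently, stacked in the fixed
  order HW1, HW2, HW3, A1, A2. Truncation takes the first T frames —
  the simplest deterministic rule.

## Classifier

A five-layer stack: sequence input of size 5; a bidirectional LSTM layer
with 100 hidden units **per direction** (the final forward state and
final backward state are concatenated to 200 features); a fully
connected layer with 3 outputs; softmax; cross-entropy loss. Gate order
is input/forget/candidate/output; input weights are Glorot-uniform,
recurrent weights per-gate orthogonal, biases zero, all drawn from the
run seed.

Training (defaults): Adam with learning rate 0.001, first-moment decay
0.9, squared-gradient decay 0.99, epsilon 1e-8; gradients clipped so
their global L2 norm never exceeds 0.9; mini-batches of 27 patterns
taken in fixed order with **no shuffling** between epochs, the partial
final batch included; up to 200 epochs; validation accuracy recorded
every 22 iterations. The final-epoch model is returned — no early
stopping or best-checkpoint selection. Everything runs in float32 on
numpy arrays, which makes training bit-reproducible for a given seed on
one CPU. Exact probability ties at prediction time resolve to the
lowest class index.

Because batches are never shuffled, a label-sorted pattern list would
give the trailing partial batch a single class every epoch and stall
learning; callers should interleave classes (the cross-validation driver
works on index sets, which are class-stratified and effectively
interleaved).

## Cross-validation and summary statistics

* **Method 1** — k near-equal folds (stratified by class when labels are
  given); every ordered pair of distinct folds (validation, test) is an
  experiment, training on the remaining k−2 folds: k·(k−1) experiments
  (272 for k=17 over 408 patterns with 360/24/24 per split; 306 for
  k=18 over 1224 with 1088/68/68).
* **Method 2** — n independent uniformly random partitions with the same
  fixed subset sizes, reproducible from the seed.
* Each experiment trains a fresh model with a seed derived from the plan
  seed and experiment index; test accuracies (%) are summarised with
  Tukey boxplot statistics: mean, sample SD, quartiles by linear
  interpolation between closest ranks, adjacent values (most extreme
  observations within 1.5·IQR of the quartiles) and the count of
  observations beyond the fences. With interpolated quartiles and
  degenerate inputs (e.g. [0, 1, 1, 1]) an adjacent value can lie beyond
  its quartile; the implementation keeps the standard definitions.

## Synthetic walker generator

The generator renders a stylized articulated walker: head (disk), trunk
(rectangle), two rigid legs swinging antiphase about the hip, two arms
swinging antiphase to the legs. Limb angles follow a *saturated* sine,
`amp · clip(κ·sin(2πft), −1, 1)`: the clipped extremes hold the extreme
pose for part of each stride, as double support does in real gait.
κ = 1.3 for legs and 2.6 for arms by default; κ = 1 recovers a pure
sinusoid.

The saturation is also a deliberate numerical choice. Pixel
rasterization quantizes widths in ±1–2 px steps; against the wide,
nearly flat top of a pure sinusoid those steps mint spurious strict
local maxima in the area ratios (A2 = gap/(h·w) is particularly exposed
because gap and width nearly cancel there). With the saturated profile
the extreme pose is bit-identical across the hold (a plateau, counted
once by the stated peak semantics) and the flanks are steep; the
stronger arm saturation locks the arm-driven full-body width at its
extreme strictly before the between-legs gap reaches its own plateau, so
the ratio denominators are exactly constant through every gap maximum.
For the same reason the arms swing 2.3× wider than the legs (they are
shorter, and must set the full-body width around the gap maxima).

Default speed classes (cycles/frame at a nominal 30 fps, leg swing in
radians) — disjoint and ordered, bracketing human stride rates at
2–7 km/h:

| class | gait frequency | leg swing |
|---|---|---|
| slow | 0.015–0.020 | 0.20–0.28 |
| normal | 0.025–0.030 | 0.28–0.36 |
| fast | 0.035–0.040 | 0.36–0.44 |

Each generated walker also draws a uniform random scale (default
0.8–1.3), so any learnable class structure cannot hide in absolute image
size. Optional noise blobs (≤3 px, Poisson-many per frame) are placed in
the lower third within the legs' own column span — where segmentation
speckle from a swinging hand appears — without touching the body, so
they exercise the denoising step without stretching any bounding box.
All randomness derives from a single seed (frame-level noise from
(seed, frame index)), making sequences bit-reproducible.

The walker is deliberately not biomechanically faithful: no knees, no
perspective, no clothing, no self-occlusion or segmentation holes, its
double-support fraction is longer than in human gait, and because the
wide-swinging arms set both the full-body and the mid-body width, HW1
and HW2 often coincide (in real silhouettes HW2 lies between HW1 and
HW3). Passing tests
on this generator therefore demonstrate that the *pipeline* recovers
known ground truth (scale invariance, gait frequency, class structure)
— not that the method reaches any particular accuracy on real video.

## Problem sizes used by the test-suite and acceptance script

The synthetic study runs three classes × 40 walkers at T = 240 and
evaluates Method 1 with k = 5 (20 train/validation/test combinations of
72/24/24) at 40 training epochs — enough for the well-separated default
classes to be learned while keeping a full run in minutes on one CPU.
The label-permutation control reuses the first 5 combinations at the
same epochs; its chance band scales with the 5×24 test predictions
involved. Scale invariance is checked per frame between each walker and
its 2× nearest-neighbour upscale; the relative deviation uses
max(|a|,|b|) as denominator (0/0 counts as 0) with an absolute floor of
0.01 on the two area ratios, below which single-pixel rasterization
effects dominate a value of magnitude ≤ 1.

## Known limitations

* The between-legs procedure assumes the crotch lies below the midline
  of the body box (true for standing humans); figures whose inter-leg
  gap reaches the crop border yield area 0 by construction.
* Amplitude and variation percentages implement one documented reading
  of loosely specified quantities (relative range; coefficient of
  variation); alternative readings rescale Tables of results but do not
  affect classification, which uses normalized signals only.
* Real-data accuracy depends on licensed datasets that are not
  redistributable; the package reads any directory-of-PNG/BMP dataset
  with a manifest, but ships validation only against its own generator.
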