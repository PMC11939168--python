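# Methods

## Scope and model

`cagecount` implements the post-detection half of a robotic cage-inspection
counting system. The underlying measurement model: a camera translates
along a row of cages at fixed speed and standoff, a detector emits
axis-aligned boxes for chicken heads and cage fences per frame, and only
**horizontal** pixel coordinates carry information about cage membership —
the camera's motion is horizontal and cages are separated by vertical
railings. All counting logic therefore operates on x-coordinates alone;
vertical extents are carried through IO but never consulted.

A cage is observed when exactly two fences are detected. The count
assigned to the cage is the maximum over its frames of the number of heads
inside the fence span. This running maximum is the occlusion-robustness
mechanism: a bird whose head is hidden in one frame is generally visible in
another during the ~3 s (~90 frames at 30 FPS and 0.2 m s⁻¹) the camera
spends on a 0.6 m cage.

## The transition rule and its semantics

The cage boundary decision is a debounced edge detector on the fence count:

- Any two-fence frame resets the streak and (re)enters the counting phase.
- Sub-two-fence frames increment a streak once counting has begun; the
  streak *reaching* N (default 10) emits the cage and resets. Shorter
  bursts are treated as detector false negatives: the running maximum is
  retained. The source description brackets the boundary with "fewer than
  ten" meaning noise and "exceeding ten" meaning a transition; reaching
  N = 10 is taken as the emission point, and N is configurable.
- Zero-fence frames advance the streak by default
  (`zero_fence_in_streak=True`); a transition that fades from 1 fence to 0
  would otherwise stall the machine between cages. Setting the flag to
  false makes zero-fence frames inert, which matches a reading in which
  only the drop *to one* fence is evidence of a passed cage.
- Frames with ≥ 3 fences are ignored entirely (no counting, streak
  untouched): the acquisition geometry guarantees at most one full cage in
  view, so such frames are detector noise.

Known failure mode (deliberately preserved and tested): a fence dropout of
≥ N frames inside a cage splits it into two records, and a genuine
inter-cage gap traversed in < N frames merges two cages into one record.
Both are inherent to any debounce threshold; N trades one against the
other.

Other contracts: "detection time" of a cage is the timestamp of its key
frame (the earliest frame attaining the maximum count), not of the
emission frame — the key frame is what is stored alongside the record.
Key-frame ties break to the earliest frame for reproducibility. At end of
stream, a pending cage with a positive running maximum is flushed so the
last cage of a row is not lost. A cage segment that never shows a head
emits `max_count = 0` with its first counting frame as key frame. The
confidence cut (default 0.25) is applied before all logic; the source
system's inference threshold is not published, so this is a package
default.

## Span and membership conventions

The fence pair induces the cage's lateral interval. The published
description says only that minimum and maximum horizontal fence
coordinates define the spatial threshold, which admits two readings; both
are implemented:

- `outer` (default): the envelope — min of both x_mins to max of both
  x_maxes. More permissive; matches the visual of heads being excluded
  only beyond the railings.
- `inner`: between the facing fence edges; raises a degenerate-span error
  if the fences overlap in x.

Head membership is likewise configurable: `center` (default; x-center
inside the closed span — robust to heads straddling a railing) or
`full_box` (whole box inside). The worked-example fixture is constructed
clear of the railings so all four combinations agree on it (8 of 11 heads
kept), and simulator placement margins guarantee noiseless parameter
recovery under every combination.

## The simulator: what it emulates, and what it does not

The generator reproduces the acquisition setup as stated: 1280 × 720
frames at 30 FPS, robot speed 0.2 m s⁻¹, cages 0.6 m wide with 5–8 birds
(occupancy uniform per cage), and a scale of 1200 px m⁻¹ so a cage spans
~720 px — the "two railings in view, never a third" regime of a ~50 cm
standoff. The world is one-dimensional: projection is pure horizontal
translation, boxes partially in view are clamped to the frame, boxes fully
outside vanish. Heads are static within a cage; the running-max code path
is exercised through occlusion noise rather than bird motion, which would
add realism but no new logic.

**Cage spacing.** Each simulated cage carries its own pair of railings.
With a 1.0667 m view width (1280 px / 1200 px m⁻¹), adjacent own-railing
cages would place four fences within one view — the camera would never see
exactly two fences and, worse, could see one cage's right fence together
with the next cage's left fence, producing phantom zero-count "cages"
between real ones. Exactly-two-fence frames require the inter-cage spacing
to be at least `(view − cage_width)/2`, and avoiding straddle pairs
requires spacing ≥ view width. The default `gap_between_cages_m = 1.2`
satisfies both, yielding per cage ~85 two-fence frames followed by a long
sub-two-fence run that triggers the transition rule naturally. A
shared-railing row (the physical arrangement in a real house) would need a
three-fence-aware front end and is out of scope. The simulator raises a
configuration error when speed/fps/geometry give fewer than one two-fence
frame per cage.

**Noise model.** Independent Bernoulli per-head misses (occlusion),
Poisson false-positive heads uniform over the frame, Gaussian shifts of
surviving head boxes, fence-dropout bursts (a per-frame probability starts
a burst that removes one fence for a sampled duration — the input the
N-frame rule exists to absorb), and an optional clipped-Gaussian
confidence model. Defaults (miss 0.05, 0.02 false heads/frame, 2 px
jitter, dropout probability 0.01 with 3–8-frame bursts, confidences
N(0.9, 0.08) clipped to [0, 1]) are package choices of a plausibly
mediocre detector: no quantitative noise rates are published. Geometry and
noise take separate seeds so one layout can be re-noised.

Consequently, passing tests demonstrate the correctness of the counting
logic under this noise family — they do not certify any particular real
detector, real lighting, bird motion, perspective effects, or cage designs
with shared railings.

## Metrics

P, R, F1 are the standard ratios; zero-denominator cases return 0 and emit
an `UndefinedMetricWarning` rather than raising, so batch evaluation never
aborts. Matching is greedy in descending confidence with one-to-one
truth assignment at an IoU threshold — standard detection practice; tests
bound its TP count against the optimal assignment. AP uses COCO-style
101-point interpolation (the AP50:95 name is a COCO convention; the exact
interpolation of the original system is framework-internal and
unpublished), evaluated per class and averaged; AP50:95 averages over IoU
0.50–0.95 in 0.05 steps. Percentages for table comparison round half-up
at one decimal. The three counting rates are plain ratios wrapped with
that formatting and a consistency-checked `CountingReport` container.

## Numerical and IO choices

Coordinates are continuous 0-based pixel floats; no half-open pixel
semantics are needed because only continuous interval tests are performed.
Span membership uses closed intervals (a head centered exactly on the span
edge is counted). Boxes partially outside a frame are clamped, not
rejected (routine at frame edges during traversal); a box that is
degenerate *before* clamping is a validation error, one that vanishes
under clamping is dropped. JSON-lines is the canonical stream dialect (one
frame per line, optional metadata header); COCO JSON and YOLO txt
directories are supported for interoperability, with YOLO class ids
0 = chicken_head, 1 = fence (overridable — no numeric ids are published).
YOLO files store normalized coordinates with 10 decimals so all three
dialects round-trip to 1e-6 in pixel space. Cage records serialize
timestamps at millisecond precision. CLI outputs embed a SHA-256 config
digest for provenance.

## Reference blocks

The two architectural ingredients of the upstream detector are provided as
training-free NumPy forward passes with structural invariants, not as
learnable modules: coordinate attention (directional mean-pooling →
shared 1×1 reduction (ratio 32, a common default; unpublished) → per-axis
1×1 maps with logistic squashing → multiplicative factors in (0, 1), so
outputs strictly attenuate and shape is preserved) and additive reversible
coupling ((x₁, x₂) → (x₂, x₁ + F(x₂)) with F a 1×1 channel map plus tanh —
the internals of F are not published at this granularity), composed into a
reversible column over a feature pyramid whose inverse reconstructs the
previous column's states exactly up to float error. Tests verify
invertibility at 1e-5 across random shapes and depths.

## Problem sizes in the test suite

The suite favours many small deterministic instances: state-machine
behaviour is checked against a brute-force flowchart interpreter on 1000
random fence-count sequences; parameter recovery runs 50 noiseless
simulations of 3–20 cages; the multi-frame vs single-frame contrast uses
5–6 cages over a four-point occlusion sweep; AP equality against an
independent reference uses 20-truth-box multi-frame sets. These sizes
exercise every code path and invariant while keeping the full suite in
well under a minute.

## Known limitations

- One cage in view at a time; shared-railing rows and multi-cage views are
  out of scope (≥ 3 fence frames are dropped, not interpreted).
- Cage localization is temporal only (timestamps); no robot-coordinate
  mapping.
- The simulator's noise is frame-independent; real occlusion is
  temporally correlated (a bird stays hidden for many consecutive frames),
  which would lower multi-frame recovery rates relative to the synthetic
  results shown by the demo.
- No video decoding or detector inference: the package begins at the
  box level.
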