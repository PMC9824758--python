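# Methods

## Problem and scope

`feedcount` estimates, per image, how many pigs in a barn are actively
feeding, given only bounding-box detections (pig heads; pig bodies labelled
`Standing`, `LyingBelly` or `LyingSide`; fixed feeder bins). It is pure
postprocessing: running or training a detector is out of scope, and a
detector adapter is a documented extension point rather than a feature.
All geometry is interpreted in the coordinate frame of the detections
supplied (real-valued pixels, origin top-left, y downward, boxes as closed
intervals), which matches YOLO- and COCO-style outputs.

## The counting model

The method rests on two behavioural facts about penned pigs. First, a
feeding pig's head is *at* the trough, so head-to-feeder IoU separates
potential feeders from the rest; proximity alone, however, is confounded by
pigs that lie idly against the feeder. Second, feeding pigs stand on four
legs — the trough is too high to reach while lying — so posture resolves
the confound. Between the two gates sits a head–body association step,
because posture is carried by body detections while trough proximity is
measured on heads.

### Candidate gate

A head is a candidate when max over feeders of IoU(head, feeder) is
**strictly greater** than `feeder_iou_threshold`. The strict inequality
means a threshold of 0 still excludes non-overlapping heads. The default
0.01 treats any genuine overlap as "at the trough"; the value is
configurable because camera geometry changes how much a feeding head
protrudes over the feeder box.

### Head–body mapping

For each head (processed in descending detection confidence, ties by input
order) the overlapping bodies (intersection area > 0) are collected and the
one whose center is farthest from the head's center is assigned, then
removed from the pool — greedy, one-to-one. The geometric rationale: a
pig's head occupies one end of its body's major axis, so its own body
center lies roughly half a body-length away, whereas an interloping
neighbour's body typically overlaps the head near that body's flank, close
to its own center. Heads with no available overlapping body yield no pair.
Distance ties break toward the lower body index.

Two deliberate design points:

* **Direction.** The default iterates heads and picks the farthest body;
  the mirrored rule (each body claims its farthest overlapping head) is
  available as `mapping_direction="body_to_head"`. Both are reasonable
  readings of the farthest-center idea; they differ only in contested
  multi-pig configurations.
* **Order.** The greedy pass is order-dependent, so a deterministic order
  is required; descending confidence makes contested bodies go to the more
  reliable head detections.

The head-coverage ratio |head ∩ body| / |head| is size-invariant across
pigs. Pairs below `head_coverage_threshold` (default 0.5) are flagged
`low_coverage` — signalling an occluded or implausibly matched head — but
retained, since a partially visible head on a standing body at the trough
is still most plausibly a feeding pig.

An optional body-only fallback (`allow_body_only_candidates`, off by
default) appends headless pairs for unconsumed bodies overlapping a feeder,
covering fully occluded heads. It is off by default because it changes the
count's failure mode from under- to over-counting when bodies merely brush
the feeder box.

### Posture gate

The count is the number of pairs whose body posture equals
`feeding_posture` (default `Standing`). `feeding_posture=None` accepts all
postures, reducing the pipeline to distance-only gating — the baseline the
posture gate exists to improve on, kept reachable for comparison.

## Evaluation: SADR

SADR = Σᵢ |Gᵢ − Pᵢ| / T sums per-image absolute count errors and
normalises once by the barn population T. It is deliberately *not* averaged
over images, so its magnitude scales with the evaluation set size; it is
comparable only across methods scored on the same image set and barn. T is
a required user input — a husbandry fact, not something inferable from
detections. Results are reported unrounded and rounded to two decimals.

## Aggregation

The diurnal profile buckets timestamped counts by hour of day and reports
the per-bin **mean** (not sum), so unequal day coverage cannot bias the
curve; bins never observed are absent, not zero. The daily series sums
counts per calendar date, and a zero-activity day is kept as data.
Timestamps are local barn time; no timezone handling is attempted. Both
aggregates count pig-image events (the sum of per-image counts), not
distinct feeding bouts — bout segmentation would need sub-hourly sampling
and identity tracking, both out of scope.

## The synthetic barn

The generator emulates the study conditions the pipeline is meant for: a
640×640 top view with two fixed feeder bins (18% × 22% of the frame,
centered on the horizontal thirds), a pen of `n_pigs = 12`, and per scene:

* each pig feeds with `p_feeding = 0.25` (hourly snapshots catch a minority
  of the pen at the trough outside mealtimes);
* feeding pigs are `Standing` with their head box overlapping a feeder by
  45–75% of the head's depth — IoU comfortably above any sensible gate;
* non-feeding pigs draw a posture (`Standing` 0.30, `LyingBelly` 0.35,
  `LyingSide` 0.35); lying pigs lie directly against a feeder with
  probability `p_lie_near_feeder = 0.5`, reproducing the proximity-only
  false positive (≈35–40% of non-feeding pigs in trap position);
* bodies are ~2:1 rectangles (short side 38–50 px) with the head box
  (0.65 of the short side) at one major-axis end, 60% inside the body —
  so head-coverage ≥ 0.5 and the farthest-center rule hold by
  construction;
* detector imperfections are opt-in: `head_dropout_prob` removes head
  boxes (occlusion), `jitter_px` perturbs box corners uniformly.

Placement is rejection-sampled so pigs never overlap one another; feeding
pigs claim trough slots first and a trap pig that finds the trough fully
occupied lies down elsewhere, so only an over-subscribed feeding draw can
make a scene infeasible (a `SimulationError` after bounded retries). Body
dimensions are re-drawn on every placement attempt, which lets a smaller
pig fit a tight slot. All randomness flows through one
`numpy.random.Generator`; identical (config, seed) reproduces scenes — and
written datasets — byte for byte.

Because clean scenes have non-overlapping pigs, gate-safe head placement
and correct-by-construction mapping geometry, the pipeline must recover the
true count on every clean scene; this exactness (SADR = 0 over any clean
batch) is the end-to-end correctness oracle, and the trap pigs make the
distance-only baseline strictly worse on the same scenes. What passing
these tests does **not** show: robustness to real detector behaviour —
overlapping pigs, correlated posture misclassification, duplicate and
spurious boxes, rotated (non-axis-aligned) animals. The dropout and jitter
knobs probe the first-order versions of such noise only.

An auxiliary deterministic constructor (`make_interleaved_scene`) builds
staggered adjacent pigs whose heads overlap two bodies each — the
configuration where proximity association fails — with the true assignment
returned for verification.

## Numerical and degenerate-input choices

* IoU of two zero-area boxes is 0, not NaN: degenerate detections flow
  through as non-candidates rather than crashing the pipeline. A zero-area
  *head* passed to the coverage ratio is an error, since the ratio is
  undefined and such a head cannot anchor a pig.
* A square body box's major axis is taken horizontal — any fixed
  convention works (the mapping rule uses center distances, not the axis
  itself), but determinism requires one.
* Boxes spilling past the image frame are clamped on read with a warning;
  detectors routinely emit them and rejection would drop real pigs.
* Validation problem sizes (10,000 oracle box pairs; 500-scene batches;
  100 timeseries; a 30-day schedule) give the acceptance checks tight
  statistics while keeping the whole suite and script runnable in seconds.

## Known limitations

* Axis-aligned boxes only; a diagonally lying pig's box axes misrepresent
  its spine, which can defeat the farthest-center heuristic. The source
  detections would need rotated boxes or masks to fix this.
* The greedy assignment is not globally optimal; pathological three-pig
  interleavings can mis-assign even when a global matching would not.
* SADR's single-T normalisation makes cross-study comparisons meaningful
  only at matched image counts.
* Feeding *events* are pig-image counts at the capture cadence; they are
  not feeding bouts or durations.
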