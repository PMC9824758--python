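# feedcount

Counting how many pigs are *actually feeding* in a barn, from ordinary
object-detection output.

Hourly top-view barn cameras plus an object detector give per-image bounding
boxes for pig heads, posture-classified pig bodies (`Standing`,
`LyingBelly`, `LyingSide`) and the fixed feeder bins. Simply counting pigs
near the trough over-counts badly: pigs love to lie idly right beside the
feeder. `feedcount` is a detector-agnostic postprocessing toolkit that turns
such detections into a reliable feeding count, scores it, and aggregates it
into the herd's feeding rhythm — a signal used for growth monitoring and
early illness detection in precision livestock farming.

## The method

For each image, with head boxes *h*, posture-labelled body boxes *b* and
feeder boxes *f*:

1. **Candidate selection (distance estimation).** Keep each head with
   IoU(h, f) = |h ∩ f| / |h ∪ f| > τ for some feeder (default τ = 0.01 —
   any genuine overlap with the trough).
2. **Head–body mapping.** Greedily assign each candidate head to the
   overlapping body whose **center is farthest** from the head's center,
   consuming the body (one-to-one). A pig's head sits at the far end of its
   body's major axis, so among overlapping bodies the farthest center
   belongs to the right pig, while a neighbour's body overlaps a head near
   its own flank. The head-coverage ratio |h ∩ b| / |h| flags occluded
   heads (size-invariant, default flag threshold 0.5).
3. **Posture filtration.** Count only pairs whose body is `Standing` —
   the trough is too high to eat from while lying. Setting
   `feeding_posture=None` disables the gate and recovers the
   distance-only baseline.

Counts are scored with the **sum of absolute difference ratio**

    SADR = Σᵢ |Gᵢ − Pᵢ| / T

(G actual, P predicted feeding count per image, T the barn population;
lower is better), and timestamped counts aggregate into a diurnal profile
(mean count per hour of day) and a daily feeding-event series.

A seeded synthetic barn generator produces detection-level scenes with
known ground truth — including the lying-at-the-trough false-positive
trap — so the whole pipeline is testable without any camera data.

## Worked example

Simulate a day of hourly scenes for a 12-pig barn, count, score, aggregate:

```sh
feedcount simulate --out-dir barn --seed 7 --n-scenes 24
feedcount count --input barn/scenes.json --format coco --out counts.csv
feedcount evaluate --pred counts.csv --truth barn/truth.csv --population 12
feedcount aggregate --counts counts.csv --out-prefix pattern --plot
```

which prints:

```
INFO feedcount: wrote 24 scenes (78 feeding-pig events) to barn
INFO feedcount: counted 24 images, 78 feeding-pig events total → counts.csv
SADR 0.0 (0 unrounded): total |G−P| = 0 over 24 images, barn population T = 12
INFO feedcount: aggregated 24 records into 24 diurnal bins and 1 days
```

On noise-free detections the pipeline recovers every ground-truth count
exactly (SADR 0.0), even though roughly a third of the non-feeding pigs
are lying directly against a feeder. With detector imperfections switched
on (10% head dropout, 3 px box jitter via a small YAML config):

```
SADR 0.5 (0.5 unrounded): total |G−P| = 6 over 24 images, barn population T = 12
```

— six pig-image errors over a day, almost all from dropped (occluded)
heads. `counts.csv` holds one row per image
(`image_id,timestamp,predicted,actual`); `pattern_diurnal.csv` and
`pattern_daily.csv` hold the aggregates.

The same works in-process:

```python
from feedcount import SimConfig, generate_batch, count_scenes

scenes, truth = generate_batch(SimConfig(), n_scenes=24, seed=7)
predictions = count_scenes(scenes)
```

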