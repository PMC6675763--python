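# cinevents

Event-structure analysis for annotated movies: narrative-shift coding,
sequence and montage detection, shot-duration profile shapes, and viewer
segmentation statistics.

## The problem

Viewers spontaneously parse a movie into events.  Scene boundaries — shot
junctures where the location, the major characters, and/or the time frame
change (*narrative shifts*) — are segmented very consistently.  But popular
films also contain *sequences*: runs of short scene-like units (subscenes)
stitched together by a repeating shift pattern and a continuous soundtrack,
such as cross-cut chases, battle alternations, and Hollywood montages.
Viewers segment the internal boundaries of sequences far less consistently
than scene boundaries, even though the shifts themselves carry the same
codes.  Quantifying that structure requires a reproducible pipeline from
shot-level annotations to boundary classes, unit-shape profiles, and
segmentation statistics — which is what this package provides, for film and
event-cognition researchers working with shot-level codings.

## What it computes

Given one row per shot (duration, 1–7 framing scale, location label,
character labels, transition/time markers, sound class):

* **Shift coding** (`cinevents.shift_coder`) — the three-place code at
  every juncture, e.g. `[L C -]` for a cross-cut (location and characters
  change, time runs continuously).  Major characters are those in > 10% of
  a movie's shots; time is inferred from travel/cross-cut rules unless the
  annotator marked it explicitly.
* **Sequence detection** (`cinevents.sequence_detector`) — units start at
  every shift; a sequence is ≥ 3 consecutive units whose ≥ 2 internal
  boundaries repeat one shift label, bound by a single sound class on every
  shot, each unit shorter than the movie's mean scene duration (threshold
  iterated with detection to a fixed point).  Montages are sequences of
  1–2-shot units.  A census tallies counts, shift-type distributions inside
  vs outside sequences, sound shares, and the count-vs-release-year trend.
* **Profile shapes** (`cinevents.profile_shapes`) — per-unit shot values
  resampled to 200 ordinal bins, averaged per movie, subsampled at 7 bins;
  quadratic ("scalloped") trend tests and a scene-vs-subscene comparison
  with movie fixed effects and cluster-robust inference.
* **Video features** (`cinevents.video_features`) — per-shot motion
  (next-adjacent frame correlation), luminance (mean per-frame median), and
  clutter (Sobel edge-pixel fraction on every tenth frame).
* **Segmentation statistics** (`cinevents.stats_models`) — per-class
  viewer segmentation rates, mean pairwise Cohen's κ, Welch *t* / Cohen's
  *d*, and the regression of segmentation consistency on music, duration,
  scale, motion, luminance, clutter with movie as a nominal factor.
* **Synthetic corpora** (`cinevents.synthetic`) — a fully ground-truthed
  generator of annotated movies, viewer responses, and frame stacks with
  the statistical structure above, so every stage is testable without any
  film data.  See `docs/methods.md` for the generator's conditions.

## Worked example

```python
from cinevents import (GeneratorConfig, generate_corpus, generate_viewer_responses,
                       code_movie, segment_units, find_sequences, classify_boundaries,
                       segmentation_rate, agreement_kappa)

cfg = GeneratorConfig(n_movies=1)
movies, truth = generate_corpus(cfg, seed=7)
movie = movies[0]
codes = code_movie(movie)
units = segment_units(movie, codes)
spans = find_sequences(movie, codes, units)
print(f"{movie.movie_id}: {movie.n_shots} shots, {len(units)} units, "
      f"{len(spans)} sequences ({sum(s.montage for s in spans)} montages)")
for s in spans:
    print(f"  units {s.units[0]}-{s.units[-1]}: {s.shift_type} x"
          f"{s.internal_boundary_count}, {s.sound_class}, montage={s.montage}")
classes = classify_boundaries(codes, units, spans)
table = generate_viewer_responses(movies, truth, cfg, seed=7)[movie.movie_id]
for cls, rate in segmentation_rate(table, classes).items():
    if rate is not None:
        print(f"  {cls}: {100 * rate:.1f}%")
print(f"  mean pairwise kappa: {agreement_kappa(table):.2f}")
```

prints

```
syn000_action_1940: 536 shots, 38 units, 2 sequences (0 montages)
  units 14-16: [L C -] x2, nondiegetic_music, montage=False
  units 27-31: [L C -] x4, nondiegetic_music, montage=False
  scene_boundary: 87.1%
  subscene_boundary: 50.0%
  within_scene: 4.1%
  mean pairwise kappa: 0.47
```

The two detected sequences are `[L C -]` alternations (locations and
characters flip while time runs continuously — the classic cross-cut),
bound by nondiegetic music.  The three simulated viewers segment ~87% of
scene boundaries but only half of the subscene boundaries inside
sequences, and almost never respond inside scenes — the planted
scene/subscene contrast this pipeline is built to measure.  κ ≈ 0.5 is the
between-viewer agreement implied by independent responding at those rates.

## Command line

```bash
cinevents simulate --seed 17 --n-movies 24 --out corpus/     # corpus + truth
cinevents code --in corpus/syn000_action_1940.json --out codes.csv
cinevents sequences --in corpus/syn000_action_1940.json --out seq.json
cinevents profiles --in corpus/ --out profiles.csv           # + .stats.json
cinevents features --frames frames/ --shots movie.json --out features.csv
cinevents analyze --corpus corpus/ --out report.json
cinevents run-all --seed 17 --out run/                       # end to end
```

`run-all` also accepts `--config run.yaml` with keys `seed`, `n_movies`,
`corpus`, `out`.  Reports are deterministic for a fixed seed; timestamps
live in a sidecar `metadata.json`.

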