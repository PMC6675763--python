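# Methods

`cinevents` analyses the event structure of popular movies from shot-level
hand annotations.  The object of study is the *sequence* — a run of short,
scene-like units (subscenes) bound together by a common soundtrack and a
repeating pattern of narrative shifts — and the way viewers segment movies
at the boundaries inside and around such structures.  This note records the
models, rules, parameter choices, and numerical decisions behind the
implementation, and what the synthetic corpus does and does not emulate.

## Narrative-shift coding

A narrative shift at a shot juncture is a change in location (L), major
characters (C), and/or time (T), coded as a three-place label such as
`[L C -]`.  Seven non-null labels plus the null `[- - -]` partition all
junctures.  The rules implemented:

* **Location** — a change of the annotated location label.  Locations are
  opaque labels; the semantics of what counts as a boundary (doors,
  geographical divides) live with the annotator.
* **Major characters** — a character is *major* when it appears in strictly
  more than 10% of the movie's shots.  C compares the major-character sets
  on the two sides, including present/absent transitions.  When neither
  side shows a major character the character code is null (C false).  The
  strict reading of "more than 10%" is a documented convention; a
  character in exactly 10% of shots is not major.
* **Time** — an explicit coder mark wins: `forward_ellipsis` and
  `backward` force T (the direction is kept only in the derivation
  record), `continuous` forces no T.  With no mark (`auto`), time is
  inferred: if the location changes while the *same non-empty* major cast
  is shown, the characters had to travel, so T is true — unless the entry
  is flagged as instantaneous transport (`teleport_in`), the
  science-fiction exception.  At cross-cuts (L and C both change) time is
  taken to run continuously, and with no location change and no mark there
  is no time change.

One subtlety: a bare "L and not C implies T" rule would wrongly mark
prologue-style junctures (location changes with no major characters on
either side) as time shifts; the travel inference therefore requires the
shared major cast to be non-empty, which also keeps `[L - -]` reachable
without an explicit `continuous` mark.

## Sequence detection

Units are maximal runs of shots with no internal narrative shift; a new
unit starts at every non-null boundary.  A *sequence* is a run of at least
three consecutive units satisfying:

1. **Repetition** — its two or more internal boundaries all carry one
   identical non-null shift label;
2. **Soundtrack binding** — one sound class (nondiegetic music, diegetic
   music, voiceover, or a pervasive ambient signal) covers every shot of
   every unit;
3. **Pace** — every unit is shorter than the movie's mean scene duration.

A *montage* is a sequence whose units all have at most 2 shots (the second
shot absorbs annotation jitter around classic single-shot alternation;
the bound is a module constant).  Multi-shot sequences require at least 3
shots in every unit; mixed unit sizes break a run.  Runs extend greedily
and maximally; a unit failing any criterion terminates the run before it.
Two maximal runs with different labels may abut or share one unit, and
when they do so under one sound class both are flagged complex
(`simple=False`); complex structures are flagged, never merged.

**Duration threshold.** "Mean scene duration" is ambiguous when the
detection itself decides which units are scenes.  The implementation
iterates: pass 1 uses the mean over all units; each later pass recomputes
the mean over units outside the currently detected sequences and re-runs
detection, stopping at a fixed point (capped at ten passes; two or three
suffice in practice).  A fixed two-pass scheme was tried first and is not
stable on sequence-rich movies: the pass-1 mean is diluted by the many
short subscene units, so pass 2 still under-detects and a third pass would
change the answer.  The fixed point makes the output insensitive to that
dilution and is testable (the result is stable under one further pass).

## Profile shapes

To compare units with different shot counts, each unit's per-shot value
vector (log10 duration, or raw 1-7 scale) is resampled onto 200 ordinal
bins: each shot occupies an equal ordinal span and a bin takes the value of
the shot it falls in (bin *j* of *n* maps to shot
`floor(((j-0.5)/n)·n_shots)+1`).  This is deliberate nearest-neighbour
assignment, not temporal interpolation — the analysis unit is the shot; a
linear-interpolation mode exists behind a flag.  Profiles are averaged
bin-wise within a movie and subsampled at bins 1, 33, 67, 100, 133, 167,
200 for inference, approximating independent samples and matching the
median subscene length (7 shots).  Only units with at least 3 shots enter
(shorter units cannot express curvature).  Durations are log10-scaled; the
base only rescales coefficients.

The quadratic trend over the seven bins is an OLS fit `y ~ 1 + x + x²`
with a joint F(2, 4) test of the linear and quadratic terms; it reproduces
an exact quadratic to < 1e-9.

The scene-vs-subscene comparison stacks each movie's 7-bin profiles for
both kinds and fits kind, centred linear and quadratic bin terms, and
kind-by-bin interactions with movie fixed effects, using cluster-robust
(by movie) covariance and t(G−1) reference distributions.  A random
intercept likelihood model would be the other natural choice; the fixed
effects + cluster-robust route is deterministic, has no convergence
failures at 20 clusters, and its level-test type-I error is calibrated
(≈ 4-5% at a nominal 5% in the null simulations the suite runs).
Geometric-mean durations per kind are reported from the 200-bin profiles,
which weight all ordinal positions equally; the 7-bin subsample
over-weights unit endpoints and would bias the means upward for scalloped
profiles.

## Low-level video measures

* **Motion** — mean Pearson correlation of next-adjacent frame pairs
  (1-3, 2-4, ...); 1.0 is static, lower is more motion.  Zero-variance
  pairs are skipped and logged.
* **Luminance** — per-frame median pixel value (0-255) averaged over
  frames.
* **Clutter** — fraction of edge pixels on every tenth frame (1, 11, 21,
  ...), averaged.  The edge operator is a Sobel gradient magnitude on
  0-1-rescaled frames thresholded at 0.1; the threshold is a fixed module
  constant so results are bit-reproducible.  No specific operator is
  canonical for this measure; Sobel-plus-threshold is this package's
  documented choice.

Colour frames are reduced with Rec.601 weights before all measures.

## Segmentation statistics

The segmentation rate of a boundary class is the viewer-averaged response
proportion: total responses over boundaries of the class divided by
(viewers × boundaries).  Boundary classes come from the detector: null
junctures are within-scene; junctures internal to a multi-shot sequence
are subscene boundaries; junctures internal to a montage are
montage-internal; all other shifts (including sequence entry/exit) are
scene boundaries.

Agreement is the mean pairwise Cohen's kappa over the viewers' 0/1
vectors; a pair with a zero-variance viewer is excluded (identical
constant vectors count as agreement 1).  Group comparisons use the Welch
t test with Satterthwaite df and pooled-SD Cohen's d.

The predictor regression treats the per-boundary mean response (a 0-1
continuous consistency measure) as the outcome of an OLS fit on music
(0/1), log10 shot duration, shot scale, motion, luminance and clutter,
with the movie as a nominal factor (dropped with a warning for a
single-movie table).  Coefficients are screened at a strict alpha of 1e-4,
appropriate to boundary counts in the thousands.  The report also includes
the R² of the reduced model with only music, duration and scale, the
three predictors that carry the signal in this literature.

## The synthetic corpus

No real film annotations are distributable (the source codings cover
copyrighted films), so the generator *is* the study condition.  Defaults:

* **Structure** — 24 movies by default (three genres × eight release years
  1940-2010), 30 scenes per movie; sequences inserted at distinct
  scene gaps at a Poisson rate with mean `3 + 9·(year−1940)/70` (grand
  mean 7.5 per movie, matching a census of 180 sequences over 24 films,
  rising linearly with year); 15% of sequences are montages (≈ 28 of 180).
  Multi-shot sequences have 3 + Poisson(1) subscenes of
  4 + min(Poisson(3), 8) shots (median 7); montages have 4 + Poisson(6)
  single-shot units (with occasional 2-shot units).  Montage length is
  within the range of classic Hollywood montages; the mean of ~10 units
  was chosen, once, so that a 20-movie corpus yields enough
  montage-internal boundaries for per-class rate estimates, and was not
  revisited.
* **Shift types** — scene-level boundary labels are drawn i.i.d. from the
  published scene-boundary distribution (37.4 / 35.2 / 0.9 / 10.0 / 0.1 /
  16.1 / 0.5 per cent over the seven types); each sequence repeats one
  label drawn from the within-sequence distribution (20.6 / 47.1 / 15.5 /
  4.4 / 1.2 / 9.6 / 2.0).
* **Durations** — per-shot log10 durations are normal (log-normal
  durations, "strongly skewed") with σ = 0.25 dex around kind-specific
  geometric means: scenes 4.78 s, subscenes 4.10 s.  Genre
  (action 4.1 s / comedy 5.5 s / drama 6.7 s) and release year
  (−0.002 dex/year) enter as contrasts centred on zero so they do not move
  the kind means.  Scenes get a scalloped profile: a centred quadratic in
  ordinal position with 0.15 dex curvature (long opening and closing
  shots); subscenes are flat.  The scallop is centred within each unit so
  curvature does not change the unit's mean log duration.
* **Sound** — every sequence is bound by one class drawn from the
  observed shares (nondiegetic .81 / diegetic .10 / voiceover .05 /
  ambient .04); half of ordinary scenes carry music, which puts music on
  well over half of all shots.
* **Viewers** — three viewers respond independently at each boundary with
  class probabilities scene .85, subscene .56, montage .15, within-scene
  .04 (the published per-class segmentation rates).

Character/location realisation guarantees the coder recovers exactly the
planted codes: a four-member major cast (every member far above the 10%
bar — verified, with a deterministic rebuild on the astronomically rare
failure), non-empty subsets per unit, and explicit time marks or the
transport flag wherever inference alone would not produce the planted time
code.  Two suppression rules keep detection aligned with ground truth:
consecutive ordinary scenes never share a sound class, and a scene
abutting a sequence never shares the sequence's class, so the binding
criterion cannot hold across any window not fully inside a planted span.

**What the generator does not emulate.**  Viewer responses are
Bernoulli-independent across viewers and boundaries, so inter-viewer
kappa is lower than real panels show (shared perceptual input correlates
real viewers); kappa is computed but not a planted quantity.  There is no
real film content: no genre semantics, no audio, no actual complex or
meta-sequences (abutting runs arise only by construction in tests), and
the within-sequence montage/subscene mixture is parameterised by class
rather than tuned to reproduce any aggregate within-sequence rate.
Passing tests therefore show that the pipeline recovers planted structure
and calibrated statistics under these idealised conditions, not that it
would reproduce any particular hand-coded corpus.

## Problem sizes and determinism

The default analysis corpus is 20 movies (~600 shots each, ~12,000
boundaries), which the whole pipeline processes in a couple of seconds;
property suites use 200-500 random movies of up to 60 shots against
brute-force oracles, and calibration suites use a few hundred to a few
thousand null replications.  All randomness flows through
`numpy.random.default_rng` seeded from a single integer; corpora,
responses and frame stacks are bit-reproducible for a fixed seed.

## Known limitations

* Boundary classes and rates are only as good as the detector; on real,
  noisier annotations the sound-binding criterion (a single uniform class
  per shot) is a coarse stand-in for perceptual "sonic flow".
* The montage bound (≤ 2 shots per unit) and the edge threshold are fixed
  conventions, configurable but not estimated.
* The shot-scale instrument is fixed as a 1-7 ordinal treated as
  interval-valued in regressions; annotation schemes with other scale
  conventions need mapping at import.
* `compare_scene_subscene` assumes at least a handful of movies contribute
  both kinds; with one kind it returns partial output (no level or
  interaction test).
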