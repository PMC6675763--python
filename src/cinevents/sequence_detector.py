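"""Scene segmentation, sequence/montage detection, and the corpus census.

Narrative shifts partition a movie into scene-level units: a new unit starts
at every non-null shift boundary.  A *sequence* is a run of at least three
consecutive units (subscenes) that meets three criteria:

1. **Repetition** — its internal boundaries (two or more) all carry the same
   narrative-shift label;
2. **Soundtrack binding** — a single sound class (music, voiceover, or a
   pervasive ambient signal) covers every shot of every unit;
3. **Pace** — every unit is shorter than the movie's mean scene duration.

A *montage* is a sequence whose units are very short (one or two shots
each); multi-shot sequences require at least three shots per unit.  Mixed
unit sizes break a run.

The mean scene duration used by criterion 3 is computed iteratively:
pass 1 averages all units and yields a provisional detection; each later
pass recomputes the mean over units outside the provisional sequences and
re-runs the detection, stopping at a fixed point (almost always reached by
pass 2 or 3; capped at ten passes).  The fixed point makes the result
insensitive to how many subscene units dilute the initial mean.

Runs extend maximally; two maximal runs with different labels can abut or
share a unit, and when they do so under the same sound class both are
flagged as a *complex* candidate (``simple=False``).  Complex sequences are
flagged, never merged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from cinevents.annotations import MovieAnnotation
from cinevents.shift_coder import BoundaryCode, code_movie, shift_distribution

__all__ = [
    "SceneUnit",
    "SequenceSpan",
    "segment_units",
    "mean_scene_duration",
    "find_sequences",
    "label_units",
    "classify_boundaries",
    "census",
    "MONTAGE_MAX_SHOTS",
    "MIN_SUBSCENE_SHOTS",
]

#: A unit with at most this many shots counts toward a montage.
MONTAGE_MAX_SHOTS = 2
#: A unit needs at least this many shots to join a multi-shot sequence.
MIN_SUBSCENE_SHOTS = 3


@dataclass(frozen=True)
class SceneUnit:
    """A maximal run of shots with no internal narrative shift."""

    unit_id: int
    first_shot: int  # 1-based, inclusive
    last_shot: int   # 1-based, inclusive
    duration_s: float
    kind: str = "scene"  # scene | subscene | montage_shot

    @property
    def n_shots(self) -> int:
        return self.last_shot - self.first_shot + 1


@dataclass(frozen=True)
class SequenceSpan:
    """A detected sequence: consecutive unit ids joined by one repeated shift."""

    units: tuple[int, ...]        # unit_ids, consecutive
    shift_type: str               # the repeated label
    montage: bool
    simple: bool
    sound_class: str

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def internal_boundary_count(self) -> int:
        return len(self.units) - 1


def segment_units(movie: MovieAnnotation, codes: Sequence[BoundaryCode]) -> list[SceneUnit]:
    """Tile the movie into units, starting a new unit at every narrative shift."""
    if len(codes) != movie.n_boundaries:
        raise ValueError("codes do not match the movie's boundary count")
    cut_after = [bc.boundary_index for bc in codes if not bc.code.is_null]
    units = []
    first = 1
    for last in cut_after + [movie.n_shots]:
        dur = sum(s.duration_s for s in movie.shots[first - 1:last])
        units.append(SceneUnit(unit_id=len(units), first_shot=first, last_shot=last,
                               duration_s=float(dur)))
        first = last + 1
    return units


def mean_scene_duration(movie: MovieAnnotation, units: Sequence[SceneUnit],
                        sequences_provisional: Iterable[SequenceSpan] = ()) -> float:
    """Mean unit duration, excluding units inside provisional sequences.

    With no provisional sequences this is the pass-1 mean over all units.
    """
    excluded = {u for span in sequences_provisional for u in span.units}
    kept = [u.duration_s for u in units if u.unit_id not in excluded]
    if not kept:  # every unit sits in a sequence; fall back to the global mean
        kept = [u.duration_s for u in units]
    return float(np.mean(kept))


def _unit_sound_class(movie: MovieAnnotation, unit: SceneUnit) -> str | None:
    """The single binding sound class covering every shot of a unit, if any."""
    sounds = {s.sound for s in movie.shots[unit.first_shot - 1:unit.last_shot]}
    if len(sounds) == 1:
        sound = next(iter(sounds))
        if sound != "none":
            return sound
    return None


def _boundary_label_at_junction(codes: Sequence[BoundaryCode],
                                units: Sequence[SceneUnit], j: int) -> str:
    """Shift label at the junction between unit ``j`` and unit ``j+1``."""
    boundary_index = units[j].last_shot  # juncture after the unit's last shot
    return codes[boundary_index - 1].code.label


def _detect(movie: MovieAnnotation, codes: Sequence[BoundaryCode],
            units: Sequence[SceneUnit], mean_scene_s: float) -> list[SequenceSpan]:
    """One detection pass at a fixed duration threshold.

    Emits every maximal run of >=3 consecutive units whose internal
    boundaries repeat one label and whose units jointly satisfy the
    duration, sound and unit-size criteria.
    """
    n = len(units)
    if n < 3:
        return []
    sound = [_unit_sound_class(movie, u) for u in units]
    dur_ok = [u.duration_s < mean_scene_s for u in units]
    size = ["mont" if u.n_shots <= MONTAGE_MAX_SHOTS
            else ("multi" if u.n_shots >= MIN_SUBSCENE_SHOTS else "mixed")
            for u in units]
    labels = [_boundary_label_at_junction(codes, units, j) for j in range(n - 1)]

    spans: list[SequenceSpan] = []
    start = 0
    while start < n - 2:
        label = labels[start]
        if (label == "[- - -]" or sound[start] is None or not dur_ok[start]
                or size[start] == "mixed"):
            start += 1
            continue
        # greedy extension: unit `end` joins while the junction label repeats
        # and the unit matches the span's sound/size/duration profile
        end = start
        while (end + 1 < n
               and labels[end] == label
               and sound[end + 1] == sound[start]
               and dur_ok[end + 1]
               and size[end + 1] == size[start]):
            end += 1
        if end - start >= 2:  # >=3 units, >=2 identical internal boundaries
            spans.append(SequenceSpan(
                units=tuple(range(start, end + 1)),
                shift_type=label,
                montage=(size[start] == "mont"),
                simple=True,
                sound_class=sound[start],
            ))
            start = end  # a different-label run may begin at the last unit
        else:
            start += 1
    return _flag_complex(spans)


def _flag_complex(spans: list[SequenceSpan]) -> list[SequenceSpan]:
    """Mark abutting/overlapping spans under one sound class as complex."""
    flagged = list(spans)
    for i in range(len(spans) - 1):
        a, b = spans[i], spans[i + 1]
        if b.units[0] - a.units[-1] <= 1 and a.sound_class == b.sound_class:
            flagged[i] = replace(flagged[i], simple=False)
            flagged[i + 1] = replace(flagged[i + 1], simple=False)
    return flagged


#: Safety cap on threshold/detection iterations.
MAX_DETECTION_PASSES = 10


def find_sequences(movie: MovieAnnotation, codes: Sequence[BoundaryCode],
                   units: Sequence[SceneUnit]) -> list[SequenceSpan]:
    """Sequence detection iterated with its duration threshold to a fixed point."""
    spans: list[SequenceSpan] = []
    prev: list[SequenceSpan] | None = None
    for _ in range(MAX_DETECTION_PASSES):
        thr = mean_scene_duration(movie, units, spans)
        spans = _detect(movie, codes, units, thr)
        if prev is not None and spans == prev:
            break
        prev = spans
    return spans


def label_units(units: Sequence[SceneUnit],
                spans: Iterable[SequenceSpan]) -> list[SceneUnit]:
    """Re-kind units given detected sequences: subscene / montage_shot / scene."""
    kind = {}
    for span in spans:
        for u in span.units:
            kind[u] = "montage_shot" if span.montage else "subscene"
    return [replace(u, kind=kind.get(u.unit_id, "scene")) for u in units]


def classify_boundaries(codes: Sequence[BoundaryCode], units: Sequence[SceneUnit],
                        spans: Iterable[SequenceSpan]) -> dict[int, str]:
    """Assign each boundary a class for the segmentation-rate analysis.

    Returns a map boundary_index -> one of ``scene_boundary``,
    ``subscene_boundary`` (inside a multi-shot sequence),
    ``montage_internal``, ``within_scene`` (null shift).  Unit junctions not
    internal to any sequence are scene boundaries, including sequence
    entry/exit junctions.
    """
    internal: dict[int, str] = {}
    for span in spans:
        cls = "montage_internal" if span.montage else "subscene_boundary"
        for a, b in zip(span.units[:-1], span.units[1:]):
            internal[units[a].last_shot] = cls
    out = {}
    for bc in codes:
        if bc.code.is_null:
            out[bc.boundary_index] = "within_scene"
        else:
            out[bc.boundary_index] = internal.get(bc.boundary_index, "scene_boundary")
    return out


def census(corpus: Sequence[tuple[MovieAnnotation, Sequence[SequenceSpan]]]) -> dict:
    """Corpus census: per-movie counts, shift distributions, sound shares, trend.

    Returns a dict with

    ``per_movie``
        list of rows (movie_id, release_year, genre, n_sequences, n_montages,
        n_simple, n_complex);
    ``shift_distribution_within`` / ``shift_distribution_outside``
        percentage distributions of the seven shift types inside vs outside
        detected sequences;
    ``sound_shares``
        share of sequences bound by each sound class;
    ``year_trend``
        Pearson r of per-movie sequence count against release year with a
        two-sided t test (``r`` is NaN when variance is degenerate).
    """
    per_movie = []
    sound_counts: Counter[str] = Counter()
    within_codes: list[BoundaryCode] = []
    outside_codes: list[BoundaryCode] = []
    for movie, spans in corpus:
        spans = list(spans)
        per_movie.append({
            "movie_id": movie.movie_id,
            "release_year": movie.release_year,
            "genre": movie.genre,
            "n_sequences": len(spans),
            "n_montages": sum(s.montage for s in spans),
            "n_simple": sum(s.simple for s in spans),
            "n_complex": sum(not s.simple for s in spans),
        })
        sound_counts.update(s.sound_class for s in spans)
        codes = code_movie(movie)
        units = segment_units(movie, codes)
        cls = classify_boundaries(codes, units, spans)
        for bc in codes:
            if bc.code.is_null:
                continue
            if cls[bc.boundary_index] in ("subscene_boundary", "montage_internal"):
                within_codes.append(bc)
            else:
                outside_codes.append(bc)

    n_spans = sum(sound_counts.values())
    result = {
        "per_movie": per_movie,
        "shift_distribution_within": (shift_distribution(within_codes)
                                      if within_codes else None),
        "shift_distribution_outside": (shift_distribution(outside_codes)
                                       if outside_codes else None),
        "sound_shares": {k: v / n_spans for k, v in sorted(sound_counts.items())}
        if n_spans else {},
    }
    if len(per_movie) >= 3:
        counts = np.array([row["n_sequences"] for row in per_movie], dtype=float)
        years = np.array([row["release_year"] for row in per_movie], dtype=float)
        if np.ptp(counts) == 0 or np.ptp(years) == 0:
            result["year_trend"] = {"r": float("nan"), "p": float("nan"),
                                    "note": "degenerate variance"}
        else:
            r, p = sps.pearsonr(counts, years)
            result["year_trend"] = {"r": float(r), "p": float(p)}
    else:
        result["year_trend"] = None
    return result
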