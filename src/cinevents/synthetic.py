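"""Ground-truthed synthetic corpora emulating annotated-movie structure.

The generator emits movies whose annotations carry the statistical
structure the analyses assume, with full ground truth, so every pipeline
stage is testable without any real film data:

* per-movie shot streams organised into scenes with embedded sequences and
  montages, inserted at a year-dependent rate;
* narrative-shift types at scene-level boundaries drawn from the
  scene-boundary distribution, and sequence-internal boundaries repeating
  one type drawn from the within-sequence distribution;
* log-normal shot durations around kind-specific geometric means (scenes
  longer than subscenes), with centred genre and release-year contrasts and
  a scalloped (positive-quadratic-in-log) duration profile for scenes but a
  flat one for subscenes;
* soundtrack binding on every sequence (class drawn from the observed
  music/voiceover shares) and music on about half of ordinary scenes;
* per-boundary Bernoulli viewer responses at class-specific probabilities.

Locations and characters are realised so that the shift coder recovers
exactly the planted codes: character sets are non-empty subsets of a small
major cast, explicit time marks (or the instantaneous-transport flag) are
placed wherever the inference rules alone would not yield the planted time
code.  Consecutive ordinary scenes never share a sound class, and a scene
abutting a planted sequence never shares the sequence's class, so the
soundtrack-binding criterion cannot hold across any window not fully inside
a planted span and detector output aligns with ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from cinevents.annotations import (
    GENRES,
    MovieAnnotation,
    ShotRecord,
    ViewerResponseTable,
)
from cinevents.shift_coder import SHIFT_LABELS, major_characters
from cinevents.video_features import FrameStack

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_corpus",
    "generate_viewer_responses",
    "generate_frame_stacks",
]


def _normalized(v: Sequence[float]) -> tuple[float, ...]:
    arr = np.asarray(v, dtype=float)
    return tuple(arr / arr.sum())

#: Shift-type shares at scene-level boundaries (outside sequences), in the
#: SHIFT_LABELS order [L C T], [L C -], [L - T], [L - -], [- C T], [- C -], [- - T].
SCENE_SHIFT_SHARES = _normalized([37.4, 35.2, 0.9, 10.0, 0.1, 16.1, 0.5])

#: Shift-type shares at boundaries inside sequences.
SEQUENCE_SHIFT_SHARES = _normalized([20.6, 47.1, 15.5, 4.4, 1.2, 9.6, 2.0])

#: Sound classes binding sequences and their shares.
SEQUENCE_SOUND_SHARES = {
    "nondiegetic_music": 0.81, "diegetic_music": 0.10,
    "voiceover": 0.05, "ambient_signal": 0.04,
}

#: Sound-class mix for music-covered ordinary scenes.
SCENE_SOUND_SHARES = {
    "nondiegetic_music": 0.80, "diegetic_music": 0.12,
    "voiceover": 0.04, "ambient_signal": 0.04,
}

#: Viewer response probability per planted boundary class.
RESPONSE_PROBS = {
    "scene_boundary": 0.85, "subscene_boundary": 0.56,
    "montage_internal": 0.15, "within_scene": 0.04,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic corpus.

    Durations are geometric means of log-normal per-shot durations, in
    seconds; curvature values are the peak-to-trough log10 contrast of the
    scalloped within-unit duration profile.
    """

    n_movies: int = 24
    years: tuple[int, ...] = (1940, 1950, 1960, 1970, 1980, 1990, 2000, 2010)
    genres: tuple[str, ...] = GENRES
    shift_type_probs_scene: tuple[float, ...] = SCENE_SHIFT_SHARES
    shift_type_probs_sequence: tuple[float, ...] = SEQUENCE_SHIFT_SHARES
    genre_mean_duration_s: Mapping[str, float] = field(
        default_factory=lambda: {"action": 4.1, "comedy": 5.5, "drama": 6.7})
    scene_mean_s: float = 4.78
    subscene_mean_s: float = 4.10
    scallop_curvature: float = 0.15     # scenes
    subscene_curvature: float = 0.0     # subscenes are flat
    log_duration_sigma: float = 0.25    # per-shot log10 scatter (dex)
    year_log_slope: float = -0.002      # dex per release year (older = longer)
    n_scenes_per_movie: int = 30
    scene_shots_poisson_mean: float = 12.0   # shots per scene = 3 + Poisson
    subscene_shots_poisson_mean: float = 3.0  # shots per subscene = 4 + min(Poisson, 8)
    sequence_rate_base: float = 3.0
    sequence_rate_year_slope: float = 9.0 / 70.0  # per year since 1940
    montage_share: float = 0.15
    montage_units_poisson_mean: float = 6.0   # units per montage = 4 + Poisson
    music_shot_share: float = 0.5       # probability an ordinary scene has music
    sequence_music_share: Mapping[str, float] = field(
        default_factory=lambda: dict(SEQUENCE_SOUND_SHARES))
    response_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(RESPONSE_PROBS))
    n_viewers: int = 3
    backward_time_share: float = 0.10   # flashback share of explicit time marks
    teleport_share: float = 0.25        # transport share of no-time location moves

    def validate(self) -> "GeneratorConfig":
        for name in ("shift_type_probs_scene", "shift_type_probs_sequence"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.size != 7 or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be 7 non-negative values summing to 1")
        for name in ("sequence_music_share", "response_probs"):
            for k, p in getattr(self, name).items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{k}]={p} outside [0, 1]")
        if abs(sum(self.sequence_music_share.values()) - 1.0) > 1e-9:
            raise ValueError("sequence_music_share must sum to 1")
        if self.subscene_mean_s >= self.scene_mean_s:
            raise ValueError("infeasible config: subscene_mean_s must be below "
                             "scene_mean_s for the pace criterion to hold")
        if self.n_movies < 1 or self.n_scenes_per_movie < 3:
            raise ValueError("need >= 1 movie and >= 3 scenes per movie")
        return self


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a generated corpus, keyed by movie_id."""

    units: Mapping[str, tuple[tuple[int, int, str], ...]]  # (first, last, kind)
    sequences: Mapping[str, tuple[dict, ...]]  # planted spans with label/montage
    boundary_classes: Mapping[str, Mapping[int, str]]
    response_probs: Mapping[str, float]


def _parse_label(label: str) -> tuple[bool, bool, bool]:
    return ("L" in label, "C" in label, "T" in label)


class _MovieBuilder:
    """Incrementally realises shots so the coder recovers planted codes."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator,
                 genre: str, year: int):
        self.cfg = cfg
        self.rng = rng
        self.genre = genre
        self.year = year
        self.cast = tuple(f"char{k}" for k in range(1, 5))
        self.loc_counter = 0
        self.location = self._new_location()
        self.characters = self._random_cast_subset()
        self.shots: list[ShotRecord] = []
        self.boundary_classes: dict[int, str] = {}
        self.unit_spans: list[tuple[int, int, str]] = []
        # centred genre / year contrasts around the kind geometric means
        logs = {g: np.log10(m) for g, m in cfg.genre_mean_duration_s.items()}
        grand = np.mean(list(logs.values()))
        self.genre_offset = logs[genre] - grand
        self.year_offset = cfg.year_log_slope * (year - np.mean(cfg.years))
        self.pending_entry: tuple[str, bool] | None = None  # (time_mark, teleport)
        self.pending_transition = "none"  # first shot of the movie

    def _new_location(self) -> str:
        self.loc_counter += 1
        return f"loc{self.loc_counter}"

    def _random_cast_subset(self, exclude: frozenset[str] | None = None) -> frozenset[str]:
        while True:
            mask = self.rng.random(len(self.cast)) < 0.5
            subset = frozenset(c for c, m in zip(self.cast, mask) if m)
            if subset and subset != exclude:
                return subset

    def apply_boundary(self, label: str, cls: str) -> None:
        """Realise one planted narrative shift before the next unit.

        Records the boundary class for the juncture that the *next* emitted
        shot will open.
        """
        L, C, T = _parse_label(label)
        if L:
            self.location = self._new_location()
        if C:
            self.characters = self._random_cast_subset(exclude=self.characters)
        travel_inferable = L and not C and bool(self.characters)
        teleport = False
        if T:
            if travel_inferable:
                mark = "auto"  # the travel rule infers the time change
            else:
                mark = ("backward" if self.rng.random() < self.cfg.backward_time_share
                        else "forward_ellipsis")
        else:
            if travel_inferable:
                if self.rng.random() < self.cfg.teleport_share:
                    mark, teleport = "auto", True
                else:
                    mark = "continuous"
            else:
                mark = "auto"
        self.pending_entry = (mark, teleport)
        self.pending_transition = "dissolve" if self.rng.random() < 0.2 else "cut"
        self.boundary_classes[len(self.shots)] = cls  # boundary after current shot

    def add_unit(self, n_shots: int, kind: str, sound: str, geomean_s: float,
                 curvature: float) -> None:
        first = len(self.shots) + 1
        centers = (np.arange(1, n_shots + 1) - 0.5) / n_shots
        q = (2.0 * centers - 1.0) ** 2
        scallop = curvature * (q - q.mean())  # centred: curvature keeps the mean
        base = (np.log10(geomean_s) + self.genre_offset + self.year_offset
                + scallop + self.rng.normal(0.0, self.cfg.log_duration_sigma, n_shots))
        durations = 10.0 ** base
        scales = np.clip(np.rint(self.rng.normal(4.0, 1.2, n_shots)), 1, 7).astype(int)
        for i in range(n_shots):
            if self.pending_entry is not None:
                mark, teleport = self.pending_entry
                transition = self.pending_transition
                self.pending_entry = None
            else:
                mark, teleport = "auto", False
                transition = "cut" if self.shots else "none"
            self.shots.append(ShotRecord(
                shot_index=len(self.shots) + 1,
                duration_s=float(durations[i]),
                scale=int(scales[i]),
                location_id=self.location,
                characters=self.characters,
                transition_in=transition,
                time_mark_in=mark,
                teleport_in=teleport,
                sound=sound,
            ))
        self.unit_spans.append((first, len(self.shots), kind))


def _choice(rng: np.random.Generator, items: Sequence[str],
            probs: Sequence[float]) -> str:
    return items[rng.choice(len(items), p=np.asarray(probs) / np.sum(probs))]


def _scene_sound(rng: np.random.Generator, cfg: GeneratorConfig,
                 banned: set[str]) -> str:
    """Sound class for an ordinary scene.

    Never repeats the previous unit's class, nor the class of a sequence
    the scene abuts; that makes the soundtrack-binding criterion fail for
    any window not fully inside a planted sequence.
    """
    if rng.random() >= cfg.music_shot_share:
        return "none"
    classes = [c for c in SCENE_SOUND_SHARES if c not in banned]
    probs = [SCENE_SOUND_SHARES[c] for c in classes]
    return _choice(rng, classes, probs)


def generate_corpus(config: GeneratorConfig | None = None, seed: int = 0,
                    ) -> tuple[list[MovieAnnotation], GroundTruth]:
    """Generate a deterministic corpus of annotated movies with ground truth."""
    cfg = (config or GeneratorConfig()).validate()
    rng = np.random.default_rng(seed)

    movies: list[MovieAnnotation] = []
    truth_units: dict[str, tuple] = {}
    truth_sequences: dict[str, tuple] = {}
    truth_classes: dict[str, dict[int, str]] = {}

    def build_movie(movie_id: str, year: int, genre: str):
        builder = _MovieBuilder(cfg, rng, genre, year)

        rate = cfg.sequence_rate_base + cfg.sequence_rate_year_slope * (year - 1940)
        n_seq = int(min(rng.poisson(rate), cfg.n_scenes_per_movie - 1))
        # distinct insertion gaps keep at least one scene between sequences
        gaps = sorted(rng.choice(cfg.n_scenes_per_movie - 1, size=n_seq,
                                 replace=False)) if n_seq else []
        seq_specs = []
        for _ in range(n_seq):
            label = _choice(rng, SHIFT_LABELS, cfg.shift_type_probs_sequence)
            montage = bool(rng.random() < cfg.montage_share)
            if montage:
                n_units = 4 + int(rng.poisson(cfg.montage_units_poisson_mean))
                unit_shots = [1 if rng.random() < 0.8 else 2 for _ in range(n_units)]
            else:
                n_units = 3 + int(rng.poisson(1.0))
                unit_shots = [4 + int(min(rng.poisson(cfg.subscene_shots_poisson_mean), 8))
                              for _ in range(n_units)]
            sound = _choice(rng, list(cfg.sequence_music_share),
                            list(cfg.sequence_music_share.values()))
            seq_specs.append({"label": label, "montage": montage,
                              "unit_shots": unit_shots, "sound": sound})

        def scene_label() -> str:
            return _choice(rng, SHIFT_LABELS, cfg.shift_type_probs_scene)

        prev_sound = "none"
        planted_spans = []
        gap_set = set(gaps)
        seq_after_scene = {}  # scene index -> upcoming sequence spec
        it = iter(seq_specs)
        for g in gaps:
            seq_after_scene[g] = next(it)
        first_unit = True
        for s in range(cfg.n_scenes_per_movie):
            if not first_unit:
                builder.apply_boundary(scene_label(), "scene_boundary")
            banned = {prev_sound}
            if s in seq_after_scene:
                banned.add(seq_after_scene[s]["sound"])
            sound = _scene_sound(rng, cfg, banned)
            n_shots = 3 + int(rng.poisson(cfg.scene_shots_poisson_mean))
            builder.add_unit(n_shots, "scene", sound, cfg.scene_mean_s,
                             cfg.scallop_curvature)
            prev_sound = sound
            first_unit = False
            if s in gap_set:
                plan = seq_after_scene[s]
                first_unit_idx = len(builder.unit_spans)
                builder.apply_boundary(scene_label(), "scene_boundary")
                internal_cls = ("montage_internal" if plan["montage"]
                                else "subscene_boundary")
                kind = "montage_shot" if plan["montage"] else "subscene"
                for k, n_shots_u in enumerate(plan["unit_shots"]):
                    if k > 0:
                        builder.apply_boundary(plan["label"], internal_cls)
                    builder.add_unit(n_shots_u, kind, plan["sound"],
                                     cfg.subscene_mean_s,
                                     cfg.subscene_curvature if not plan["montage"]
                                     else 0.0)
                planted_spans.append({
                    "units": tuple(range(first_unit_idx,
                                         first_unit_idx + len(plan["unit_shots"]))),
                    "shift_type": plan["label"],
                    "montage": plan["montage"],
                    "sound_class": plan["sound"],
                })
                prev_sound = plan["sound"]

        movie = MovieAnnotation(movie_id=movie_id, release_year=year, genre=genre,
                                shots=tuple(builder.shots)).validate()
        if major_characters(movie) != frozenset(builder.cast):
            return None  # a cast member missed the >10% bar; rebuild
        return movie, builder, planted_spans

    for m in range(cfg.n_movies):
        year = cfg.years[m % len(cfg.years)]
        genre = cfg.genres[m % len(cfg.genres)]
        movie_id = f"syn{m:03d}_{genre}_{year}"
        # tiny configs can leave a planted major under the appearance
        # threshold; rebuilding keeps the planted codes recoverable
        for _attempt in range(50):
            built = build_movie(movie_id, year, genre)
            if built is not None:
                break
        else:
            raise RuntimeError(f"{movie_id}: could not realise a cast in which "
                               "every member clears the major-character threshold")
        movie, builder, planted_spans = built
        movies.append(movie)
        n_b = movie.n_boundaries
        classes = {b: builder.boundary_classes.get(b, "within_scene")
                   for b in range(1, n_b + 1)}
        truth_units[movie_id] = tuple(builder.unit_spans)
        truth_sequences[movie_id] = tuple(planted_spans)
        truth_classes[movie_id] = classes

    truth = GroundTruth(units=truth_units, sequences=truth_sequences,
                        boundary_classes=truth_classes,
                        response_probs=dict(cfg.response_probs))
    return movies, truth


def generate_viewer_responses(corpus: Sequence[MovieAnnotation], truth: GroundTruth,
                              config: GeneratorConfig | None = None, seed: int = 0,
                              ) -> dict[str, ViewerResponseTable]:
    """Bernoulli viewer responses at each boundary's class probability.

    Viewers respond independently of each other and across boundaries.
    """
    cfg = (config or GeneratorConfig()).validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    tables = {}
    for movie in corpus:
        classes = truth.boundary_classes[movie.movie_id]
        responses = {}
        for b in range(1, movie.n_boundaries + 1):
            p = cfg.response_probs[classes[b]]
            responses[b] = tuple(int(v) for v in rng.random(cfg.n_viewers) < p)
        tables[movie.movie_id] = ViewerResponseTable(
            movie_id=movie.movie_id, n_viewers=cfg.n_viewers,
            responses=responses).validate(n_shots=movie.n_shots)
    return tables


def generate_frame_stacks(spec: Sequence[Mapping[str, float]], seed: int = 0,
                          size: tuple[int, int] = (96, 96), n_frames: int = 25,
                          ) -> list[FrameStack]:
    """Synthetic grayscale frame stacks with controllable feature levels.

    Each spec entry gives ``motion_level``, ``luminance_level`` and
    ``clutter_level``.  A smooth random texture field drifts horizontally in
    proportion to ``motion_level`` (0 gives perfectly static, identical
    frames); ``clutter_level`` adds vertical contrast stripes whose edges
    raise the edge-pixel fraction; frames are offset so every frame's median
    pixel equals ``luminance_level`` exactly (median shifts do not affect
    the motion correlation or edge response).  All stacks of one call share
    the texture field realisation, which makes the measured motion,
    luminance and clutter monotone in the requested levels (a field's
    autocorrelation is monotone over small integer shifts, so a common
    field gives a common, monotone shift-response curve).
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    h, w = size
    field2d = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=3.0, mode="wrap")
    field2d *= 20.0 / max(field2d.std(), 1e-12)
    stacks = []
    for entry in spec:
        motion = float(entry.get("motion_level", 0.0))
        lum = float(entry.get("luminance_level", 128.0))
        clutter = float(entry.get("clutter_level", 0.0))
        n_stripes = int(round(clutter * 16))
        stripes = np.zeros((h, w))
        if n_stripes > 0:
            cols = (np.arange(w) * (2 * n_stripes) // w) % 2
            stripes[:, cols == 1] = 30.0
            stripes[:, cols == 0] = -30.0
        frames = []
        for i in range(n_frames):
            shift = int(round(i * motion * 2.0))
            frame = np.roll(field2d, shift, axis=1) + stripes
            frame = frame - np.median(frame) + lum
            frames.append(np.clip(frame, 0.0, 255.0))
        stacks.append(FrameStack(frames=tuple(frames)))
    return stacks
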