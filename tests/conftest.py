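"""Shared fixtures and independent oracle implementations.

The oracles here re-derive the coding and detection rules in a deliberately
different, straight-line style so the package implementations can be checked
against them on random inputs.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from cinevents.annotations import MovieAnnotation, ShotRecord
from cinevents.synthetic import GeneratorConfig, generate_corpus


def make_movie(rows, movie_id="m", year=2000, genre="drama") -> MovieAnnotation:
    """Build a movie from terse per-shot tuples.

    Each row is ``(duration, location, characters)`` optionally followed by
    a dict of ShotRecord overrides.
    """
    shots = []
    for i, row in enumerate(rows, start=1):
        duration, loc, chars = row[:3]
        extra = dict(row[3]) if len(row) > 3 else {}
        extra.setdefault("transition_in", "none" if i == 1 else "cut")
        shots.append(ShotRecord(
            shot_index=i, duration_s=float(duration),
            scale=extra.pop("scale", 4), location_id=loc,
            characters=frozenset(chars), **extra))
    return MovieAnnotation(movie_id=movie_id, release_year=year, genre=genre,
                           shots=tuple(shots)).validate()


def random_movie(rng: np.random.Generator, n_shots: int | None = None) -> MovieAnnotation:
    """A fully random small movie: adversarial input for the rule oracles."""
    n = int(n_shots or rng.integers(2, 51))
    locs = ["a", "b", "c"]
    cast = ["p1", "p2", "p3", "p4", "p5"]
    sounds = ["nondiegetic_music", "diegetic_music", "voiceover",
              "ambient_signal", "none"]
    shots = []
    sound = sounds[rng.integers(5)]
    for i in range(1, n + 1):
        if rng.random() < 0.4:  # sound persists across shots more often than not
            sound = sounds[rng.integers(5)]
        chars = frozenset(c for c in cast if rng.random() < 0.4)
        mark = rng.choice(["auto", "auto", "auto", "continuous",
                           "forward_ellipsis", "backward"])
        shots.append(ShotRecord(
            shot_index=i,
            duration_s=float(10 ** rng.normal(0.6, 0.35)),
            scale=int(rng.integers(1, 8)),
            location_id=locs[rng.integers(3)],
            characters=chars,
            transition_in="none" if i == 1 else str(rng.choice(["cut", "dissolve"])),
            time_mark_in=str(mark),
            teleport_in=bool(rng.random() < 0.05),
            sound=str(sound),
        ))
    return MovieAnnotation(movie_id="rand", release_year=2000, genre="drama",
                           shots=tuple(shots)).validate()


# ---------------------------------------------------------------------------
# independent oracles

def oracle_code_movie(movie: MovieAnnotation) -> list[tuple[bool, bool, bool]]:
    """Straight-line re-derivation of the narrative-shift rules."""
    counts: Counter[str] = Counter()
    for shot in movie.shots:
        for c in shot.characters:
            counts[c] += 1
    majors = set()
    for c, k in counts.items():
        if k > 0.10 * len(movie.shots):
            majors.add(c)
    out = []
    for prev, nxt in zip(movie.shots, movie.shots[1:]):
        L = prev.location_id != nxt.location_id
        mp = set(prev.characters) & majors
        mn = set(nxt.characters) & majors
        if len(mp) == 0 and len(mn) == 0:
            C = False
        else:
            C = mp != mn
        mark = nxt.time_mark_in
        if mark == "forward_ellipsis" or mark == "backward":
            T = True
        elif mark == "continuous":
            T = False
        elif L and (not C) and len(mp) > 0 and not nxt.teleport_in:
            T = True
        else:
            T = False
        out.append((L, C, T))
    return out


def oracle_sequences(movie, codes, units, threshold):
    """Enumerate every window and test the three criteria declaratively.

    Returns the set of maximal valid windows as
    ``(unit_ids, label, montage, sound_class)`` tuples.
    """
    n = len(units)
    labels = [codes[units[j].last_shot - 1].code.label for j in range(n - 1)]

    def unit_sound(u):
        classes = {s.sound for s in movie.shots[u.first_shot - 1:u.last_shot]}
        if len(classes) == 1 and "none" not in classes:
            return classes.pop()
        return None

    def valid(a, b):
        labs = {labels[j] for j in range(a, b)}
        if len(labs) != 1 or "[- - -]" in labs:
            return None
        span_units = units[a:b + 1]
        sizes = set()
        for u in span_units:
            if u.duration_s >= threshold:
                return None
            if unit_sound(u) is None:
                return None
            sizes.add("mont" if u.n_shots <= 2 else
                      ("multi" if u.n_shots >= 3 else "mixed"))
        if len({unit_sound(u) for u in span_units}) != 1 or sizes == {"mixed"} \
                or len(sizes) != 1:
            return None
        return (labels[a], "mont" in sizes, unit_sound(span_units[0]))

    windows = {}
    for a in range(n):
        for b in range(a + 2, n):
            v = valid(a, b)
            if v is not None:
                windows[(a, b)] = v
    maximal = set()
    for (a, b), v in windows.items():
        contained = any((a2 <= a and b <= b2 and (a2, b2) != (a, b))
                        for (a2, b2) in windows)
        if not contained:
            maximal.add((tuple(range(a, b + 1)), v[0], v[1], v[2]))
    return maximal


def oracle_two_pass(movie, codes, units):
    """Fixed-point detection using the window-enumeration oracle."""
    spans = set()
    prev = None
    for _ in range(10):
        excluded = {u for span in spans for u in span[0]}
        kept = [u.duration_s for u in units if u.unit_id not in excluded]
        thr = float(np.mean(kept)) if kept else float(
            np.mean([u.duration_s for u in units]))
        spans = oracle_sequences(movie, codes, units, thr)
        if prev is not None and spans == prev:
            break
        prev = spans
    return spans


# ---------------------------------------------------------------------------
# shared corpora (session-scoped: generation is the expensive step)

@pytest.fixture(scope="session")
def default_corpus_20():
    cfg = GeneratorConfig(n_movies=20)
    movies, truth = generate_corpus(cfg, seed=0)
    return cfg, movies, truth


@pytest.fixture(scope="session")
def small_corpus():
    cfg = GeneratorConfig(n_movies=8, n_scenes_per_movie=10)
    movies, truth = generate_corpus(cfg, seed=3)
    return cfg, movies, truth
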