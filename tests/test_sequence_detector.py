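"""Unit segmentation, sequence/montage detection, and the census."""

import numpy as np
import pytest
from scipy import stats as sps

from cinevents.sequence_detector import (
    census,
    classify_boundaries,
    find_sequences,
    label_units,
    mean_scene_duration,
    segment_units,
    _detect,
)
from cinevents.shift_coder import code_movie
from cinevents.synthetic import GeneratorConfig, generate_corpus

from conftest import make_movie, oracle_two_pass, random_movie


def _pipeline(movie):
    codes = code_movie(movie)
    units = segment_units(movie, codes)
    spans = find_sequences(movie, codes, units)
    return codes, units, spans


def test_segment_units_examples():
    # [- - -], [L C -], [- - -] over 4 shots -> units {1-2}, {3-4}
    movie = make_movie([
        (1, "a", ["A"]), (1, "a", ["A"]), (1, "b", ["B"]), (1, "b", ["B"]),
    ])
    codes = code_movie(movie)
    assert [bc.code.label for bc in codes] == ["[- - -]", "[L C -]", "[- - -]"]
    units = segment_units(movie, codes)
    assert [(u.first_shot, u.last_shot) for u in units] == [(1, 2), (3, 4)]
    assert units[0].duration_s == pytest.approx(2.0)

    flat = make_movie([(1, "a", ["A"])] * 5)
    only = segment_units(flat, code_movie(flat))
    assert len(only) == 1 and (only[0].first_shot, only[0].last_shot) == (1, 5)


def test_units_tile_the_movie_on_random_input():
    rng = np.random.default_rng(3)
    for _ in range(50):
        movie = random_movie(rng)
        units = segment_units(movie, code_movie(movie))
        shots = [s for u in units for s in range(u.first_shot, u.last_shot + 1)]
        assert shots == list(range(1, movie.n_shots + 1))
        for u in units:
            expect = sum(s.duration_s for s in movie.shots[u.first_shot - 1:u.last_shot])
            assert u.duration_s == pytest.approx(expect)


def test_mean_scene_duration_two_pass():
    movie = make_movie([(10, "a", ["A"]), (20, "b", ["B"])])
    codes = code_movie(movie)
    units = segment_units(movie, codes)
    assert mean_scene_duration(movie, units) == pytest.approx(15.0)


def _sequence_movie(n_subscenes=4, subscene_shots=3, music="nondiegetic_music"):
    """One long silent scene then alternating short music-bound subscenes."""
    rows = [(30.0, "base", ["A"]) for _ in range(3)]
    for k in range(n_subscenes):
        loc = f"s{k}"
        chars = ["A"] if k % 2 == 0 else ["B"]
        for _ in range(subscene_shots):
            rows.append((1.0, loc, chars, {"sound": music}))
    return make_movie(rows)


def test_find_sequences_basic_alternation():
    """[L C -] alternation under continuous music is one simple sequence."""
    movie = _sequence_movie()
    codes, units, spans = _pipeline(movie)
    assert len(spans) == 1
    span = spans[0]
    assert span.shift_type == "[L C -]"
    assert span.n_units == 4
    assert not span.montage and span.simple
    assert span.sound_class == "nondiegetic_music"
    labeled = label_units(units, spans)
    assert [u.kind for u in labeled] == ["scene"] + ["subscene"] * 4


def test_alternating_labels_break_the_run():
    # [L C -], [L C T], [L C -]: no two successive identical shifts
    rows = [(30.0, "base", ["A"])] * 3
    specs = [("s0", ["A"], "auto"), ("s1", ["B"], "auto"),
             ("s2", ["A"], "forward_ellipsis"), ("s3", ["B"], "auto")]
    for loc, chars, mark in specs:
        for i in range(3):
            rows.append((1.0, loc, chars,
                         {"sound": "nondiegetic_music",
                          "time_mark_in": mark if i == 0 else "auto"}))
    movie = make_movie(rows)
    _, _, spans = _pipeline(movie)
    assert spans == []


def test_sound_binding_required():
    movie = _sequence_movie(music="none")
    _, _, spans = _pipeline(movie)
    assert spans == []


def test_duration_criterion_required():
    # subscenes as long as the scenes: pace criterion fails
    rows = [(3.0, "base", ["A"]) for _ in range(3)]
    for k in range(4):
        chars = ["A"] if k % 2 == 0 else ["B"]
        rows += [(30.0, f"s{k}", chars, {"sound": "nondiegetic_music"})] * 3
    movie = make_movie(rows)
    _, _, spans = _pipeline(movie)
    assert spans == []


def test_montage_detection_single_shot_units():
    rows = [(30.0, "base", ["A", "B"]) for _ in range(3)]
    # same cast trekking through locations: [L - T] repeated, music bound
    for k in range(5):
        rows.append((2.0, f"stop{k}", ["A", "B"], {"sound": "nondiegetic_music"}))
    movie = make_movie(rows)
    codes, units, spans = _pipeline(movie)
    assert len(spans) == 1
    assert spans[0].montage
    assert spans[0].shift_type == "[L - T]"
    assert all(units[u].n_shots <= 2 for u in spans[0].units)
    labeled = label_units(units, spans)
    assert {u.kind for u in labeled[1:]} == {"montage_shot"}


def test_classify_boundaries_partition():
    movie = _sequence_movie()
    codes, units, spans = _pipeline(movie)
    classes = classify_boundaries(codes, units, spans)
    assert set(classes) == set(range(1, movie.n_shots))
    assert sorted(set(classes.values())) == sorted(
        {"within_scene", "scene_boundary", "subscene_boundary"})
    # entry junction is a scene boundary; internal ones are subscene
    assert classes[3] == "scene_boundary"
    assert classes[6] == "subscene_boundary"


def test_detector_equals_bruteforce_oracle_random():
    """Greedy detector = exhaustive window enumeration on random movies."""
    rng = np.random.default_rng(77)
    n_checked = 0
    for _ in range(300):
        movie = random_movie(rng, n_shots=int(rng.integers(10, 61)))
        codes = code_movie(movie)
        units = segment_units(movie, codes)
        spans = find_sequences(movie, codes, units)
        got = {(s.units, s.shift_type, s.montage, s.sound_class) for s in spans}
        assert got == oracle_two_pass(movie, codes, units)
        n_checked += len(got)
    assert n_checked > 0  # the random stream must actually exercise detection


def test_detector_equals_bruteforce_oracle_structured(small_corpus):
    """Same equivalence on generator movies rich in planted sequences."""
    _, movies, _ = small_corpus
    for movie in movies:
        codes = code_movie(movie)
        units = segment_units(movie, codes)
        spans = find_sequences(movie, codes, units)
        got = {(s.units, s.shift_type, s.montage, s.sound_class) for s in spans}
        assert got == oracle_two_pass(movie, codes, units)


def test_span_structure_invariants(default_corpus_20):
    _, movies, _ = default_corpus_20
    for movie in movies[:8]:
        codes, units, spans = _pipeline(movie)
        seen_junctions = set()
        for s in spans:
            assert s.n_units >= 3 and s.internal_boundary_count >= 2
            sizes = [units[u].n_shots for u in s.units]
            if s.montage:
                assert max(sizes) <= 2
            else:
                assert min(sizes) >= 3
            junctions = set(zip(s.units[:-1], s.units[1:]))
            assert not junctions & seen_junctions  # no shared internal boundary
            seen_junctions |= junctions


def test_two_pass_is_stable_under_a_third_pass(default_corpus_20):
    _, movies, _ = default_corpus_20
    for movie in movies:
        codes = code_movie(movie)
        units = segment_units(movie, codes)
        final = find_sequences(movie, codes, units)
        thr3 = mean_scene_duration(movie, units, final)
        third = _detect(movie, codes, units, thr3)
        assert {(s.units, s.shift_type) for s in third} == \
               {(s.units, s.shift_type) for s in final}


def test_planted_sequence_recovery(default_corpus_20):
    """Detector recovers planted spans with precision/recall >= 0.95."""
    _, movies, truth = default_corpus_20
    planted = detected = hits = 0
    for movie in movies:
        _, _, spans = _pipeline(movie)
        t = {(tuple(s["units"]), s["shift_type"], s["montage"])
             for s in truth.sequences[movie.movie_id]}
        d = {(s.units, s.shift_type, s.montage) for s in spans}
        planted += len(t)
        detected += len(d)
        hits += len(t & d)
    assert hits / planted >= 0.95   # recall
    assert hits / detected >= 0.95  # precision


def test_abutting_runs_flagged_complex():
    """Two back-to-back runs under one sound class are complex candidates."""
    rows = [(60.0, "base", ["A", "B"]) for _ in range(3)]
    for k in range(3):  # [L C -] alternation, 3-shot units
        chars = ["A"] if k % 2 == 0 else ["B"]
        rows += [(1.0, f"x{k}", chars, {"sound": "voiceover"})] * 3
    # same cast continues: [L - T] trek under the same voiceover
    last_chars = ["A"]
    for k in range(3):
        rows += [(1.0, f"y{k}", last_chars, {"sound": "voiceover"})] * 3
    movie = make_movie(rows)
    _, _, spans = _pipeline(movie)
    assert len(spans) == 2
    assert {s.shift_type for s in spans} == {"[L C -]", "[L - T]"}
    assert all(not s.simple for s in spans)


def test_census_perfect_linear_trend():
    corpus = []
    for i, year in enumerate([1990, 2000, 2010]):
        movie = _sequence_movie()
        movie = make_movie(
            [(s.duration_s, s.location_id, sorted(s.characters),
              {"sound": s.sound, "time_mark_in": s.time_mark_in})
             for s in movie.shots], movie_id=f"m{i}", year=year)
        codes, units, spans = _pipeline(movie)
        corpus.append((movie, spans * (i + 1)))  # counts 1, 2, 3
    out = census(corpus)
    assert out["year_trend"]["r"] == pytest.approx(1.0)
    counts = [row["n_sequences"] for row in out["per_movie"]]
    assert counts == [1, 2, 3]


def test_census_degenerate_variance_reported():
    movie = _sequence_movie()
    corpus = []
    for i in range(3):
        m = make_movie(
            [(s.duration_s, s.location_id, sorted(s.characters),
              {"sound": s.sound}) for s in movie.shots], movie_id=f"m{i}", year=2000)
        codes, units, spans = _pipeline(m)
        corpus.append((m, spans))
    out = census(corpus)
    assert np.isnan(out["year_trend"]["r"])


def test_census_recovers_planted_year_slope(default_corpus_20):
    """Sequence counts rise with release year as planted (r > 0, p < .05)."""
    cfg, movies, truth = default_corpus_20
    corpus = []
    for movie in movies:
        _, _, spans = _pipeline(movie)
        corpus.append((movie, spans))
    out = census(corpus)
    assert out["year_trend"]["r"] > 0.3
    assert out["year_trend"]["p"] < 0.05
    # sound-class shares should echo the configured sequence mix
    assert max(out["sound_shares"], key=out["sound_shares"].get) == "nondiegetic_music"
    assert out["sound_shares"]["nondiegetic_music"] == pytest.approx(0.81, abs=0.12)


def test_table_column_correlation_matches_published_value():
    """Scene-boundary vs within-sequence shift shares correlate at r = .77."""
    excluding = [37.4, 35.2, 0.9, 10.0, 0.1, 16.1, 0.5]
    within = [20.6, 47.1, 15.5, 4.4, 1.2, 9.6, 2.0]
    r, _ = sps.pearsonr(excluding, within)
    assert r == pytest.approx(0.77, abs=0.005)
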