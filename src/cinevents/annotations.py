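"""Annotation data model and validated readers/writers.

A movie is annotated as an ordered list of shots.  Each shot carries the
attributes needed downstream: its duration, framing scale, location label,
the set of character labels on screen, how it was entered (transition and
time marker), and the class of sound covering it.  Viewer segmentation data
are per-boundary 0/1 responses for a small panel of viewers.

Boundary indexing convention: boundary ``i`` is the juncture between shot
``i`` and shot ``i + 1`` (1-based), so a movie with ``n`` shots has
``n - 1`` boundaries.

File dialects
-------------
JSON is the canonical lossless form: a single object with ``movie_id``,
``release_year``, ``genre`` and a ``shots`` array, fields in a fixed order,
character sets serialised as sorted lists (an empty set is ``[]``, never
``null``).  CSV is a flat UTF-8 table with one row per shot; the movie-level
fields repeat on every row and the ``characters`` field joins labels with
semicolons.  Viewer responses use a long-format CSV with columns
``movie_id, boundary_index, viewer_id, response``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "AnnotationError",
    "ShotRecord",
    "MovieAnnotation",
    "ViewerResponseTable",
    "read_movie",
    "write_movie",
    "read_responses",
    "write_responses",
    "TRANSITIONS",
    "TIME_MARKS",
    "SOUND_CLASSES",
    "GENRES",
]

TRANSITIONS = ("cut", "dissolve", "fade", "wipe", "none")
TIME_MARKS = ("auto", "continuous", "forward_ellipsis", "backward")
SOUND_CLASSES = ("nondiegetic_music", "diegetic_music", "voiceover", "ambient_signal", "none")
GENRES = ("action", "comedy", "drama")

#: Sound classes that can bind a sequence (everything except silence).
BINDING_SOUND_CLASSES = SOUND_CLASSES[:-1]


class AnnotationError(ValueError):
    """Validation failure, addressable to a row/field of the offending record.

    Parameters
    ----------
    message:
        Human-readable description.
    row:
        1-based shot index (or CSV data row) at fault, when known.
    field:
        Name of the offending field, when known.
    """

    def __init__(self, message: str, row: int | None = None, field: str | None = None):
        self.row = row
        self.field = field
        prefix = ""
        if row is not None:
            prefix += f"row {row}: "
        if field is not None:
            prefix += f"field '{field}': "
        super().__init__(prefix + message)


@dataclass(frozen=True)
class ShotRecord:
    """One annotated shot.

    ``scale`` is a 1-7 ordinal framing code (1 = extreme close-up,
    7 = extreme long shot).  ``time_mark_in`` describes the time relation to
    the previous shot: ``auto`` delegates the time code to the coding rules,
    while ``continuous`` / ``forward_ellipsis`` / ``backward`` are explicit
    coder judgments that override them.  ``teleport_in`` marks an
    instantaneous-transport entry (location changes with the same characters
    but no time change).
    """

    shot_index: int
    duration_s: float
    scale: int
    location_id: str
    characters: frozenset[str] = field(default_factory=frozenset)
    transition_in: str = "cut"
    time_mark_in: str = "auto"
    teleport_in: bool = False
    sound: str = "none"

    def validate(self) -> None:
        if not isinstance(self.shot_index, int) or self.shot_index < 1:
            raise AnnotationError("shot_index must be a positive integer",
                                  row=self.shot_index, field="shot_index")
        if not (float(self.duration_s) > 0.0):
            raise AnnotationError(f"duration must be > 0, got {self.duration_s!r}",
                                  row=self.shot_index, field="duration_s")
        if not isinstance(self.scale, int) or not 1 <= self.scale <= 7:
            raise AnnotationError(f"scale must be an integer in 1..7, got {self.scale!r}",
                                  row=self.shot_index, field="scale")
        if self.transition_in not in TRANSITIONS:
            raise AnnotationError(f"unknown transition {self.transition_in!r}",
                                  row=self.shot_index, field="transition_in")
        if self.time_mark_in not in TIME_MARKS:
            raise AnnotationError(f"unknown time mark {self.time_mark_in!r}",
                                  row=self.shot_index, field="time_mark_in")
        if self.sound not in SOUND_CLASSES:
            raise AnnotationError(f"unknown sound class {self.sound!r}",
                                  row=self.shot_index, field="sound")


@dataclass(frozen=True)
class MovieAnnotation:
    """A fully annotated movie: ordered, gapless shots plus corpus metadata."""

    movie_id: str
    release_year: int
    genre: str
    shots: tuple[ShotRecord, ...]

    @property
    def n_shots(self) -> int:
        return len(self.shots)

    @property
    def n_boundaries(self) -> int:
        return len(self.shots) - 1

    @property
    def total_duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.shots))

    def validate(self) -> "MovieAnnotation":
        if len(self.shots) < 2:
            raise AnnotationError("a movie needs at least 2 shots")
        if not 1900 <= int(self.release_year) <= 2100:
            raise AnnotationError(f"release_year {self.release_year} outside 1900-2100",
                                  field="release_year")
        if self.genre not in GENRES:
            raise AnnotationError(f"unknown genre {self.genre!r}", field="genre")
        for i, shot in enumerate(self.shots, start=1):
            if shot.shot_index != i:
                raise AnnotationError(
                    f"shot_index must be gapless and 1-based; expected {i}, got {shot.shot_index}",
                    row=i, field="shot_index")
            shot.validate()
        if self.shots[0].transition_in != "none":
            raise AnnotationError("first shot must have transition_in='none'",
                                  row=1, field="transition_in")
        for shot in self.shots[1:]:
            if shot.transition_in == "none":
                raise AnnotationError("only the first shot may have transition_in='none'",
                                      row=shot.shot_index, field="transition_in")
        return self


@dataclass(frozen=True)
class ViewerResponseTable:
    """Per-boundary 0/1 segmentation responses for each of ``n_viewers``.

    ``responses[b]`` is the tuple of per-viewer responses at boundary ``b``;
    the per-boundary count therefore lies in ``0..n_viewers``.
    """

    movie_id: str
    n_viewers: int
    responses: Mapping[int, tuple[int, ...]]

    def validate(self, n_shots: int | None = None) -> "ViewerResponseTable":
        if self.n_viewers < 1:
            raise AnnotationError("n_viewers must be >= 1", field="n_viewers")
        for b, votes in self.responses.items():
            if b < 1 or (n_shots is not None and b > n_shots - 1):
                raise AnnotationError(f"boundary_index {b} out of range", row=b,
                                      field="boundary_index")
            if len(votes) != self.n_viewers:
                raise AnnotationError(
                    f"expected {self.n_viewers} responses at boundary {b}, got {len(votes)}",
                    row=b, field="response")
            if any(v not in (0, 1) for v in votes):
                raise AnnotationError(f"responses must be 0/1 at boundary {b}", row=b,
                                      field="response")
        return self

    def counts(self) -> dict[int, int]:
        """Per-boundary number of viewers who segmented (0..n_viewers)."""
        return {b: int(sum(v)) for b, v in self.responses.items()}


# ---------------------------------------------------------------------------
# serialisation helpers

_SHOT_FIELDS = ("shot_index", "duration_s", "scale", "location_id", "characters",
                "transition_in", "time_mark_in", "teleport_in", "sound")


def _shot_to_dict(shot: ShotRecord) -> dict:
    return {
        "shot_index": shot.shot_index,
        "duration_s": shot.duration_s,
        "scale": shot.scale,
        "location_id": shot.location_id,
        "characters": sorted(shot.characters),
        "transition_in": shot.transition_in,
        "time_mark_in": shot.time_mark_in,
        "teleport_in": bool(shot.teleport_in),
        "sound": shot.sound,
    }


def _shot_from_dict(d: dict, row: int) -> ShotRecord:
    try:
        chars = d["characters"]
        if chars is None:
            raise AnnotationError("characters must be a list, not null", row=row,
                                  field="characters")
        return ShotRecord(
            shot_index=int(d["shot_index"]),
            duration_s=float(d["duration_s"]),
            scale=int(d["scale"]),
            location_id=str(d["location_id"]),
            characters=frozenset(str(c) for c in chars),
            transition_in=str(d["transition_in"]),
            time_mark_in=str(d["time_mark_in"]),
            teleport_in=bool(d["teleport_in"]),
            sound=str(d["sound"]),
        )
    except KeyError as exc:
        raise AnnotationError(f"missing required column {exc.args[0]!r}", row=row,
                              field=exc.args[0]) from exc
    except (TypeError, ValueError) as exc:
        if isinstance(exc, AnnotationError):
            raise
        raise AnnotationError(str(exc), row=row) from exc


def read_movie(path: str | Path, format: str | None = None) -> MovieAnnotation:
    """Read a movie annotation from JSON (canonical) or CSV.

    ``format`` defaults to the file suffix.  The result is validated; a
    malformed row raises :class:`AnnotationError` naming the row and field.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        shots = tuple(_shot_from_dict(d, row=i)
                      for i, d in enumerate(doc.get("shots", []), start=1))
        movie = MovieAnnotation(movie_id=str(doc["movie_id"]),
                                release_year=int(doc["release_year"]),
                                genre=str(doc["genre"]), shots=shots)
    elif fmt == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            rows = list(csv.DictReader(fh))
        if not rows:
            raise AnnotationError("empty CSV file")
        shots = []
        for i, row in enumerate(rows, start=1):
            d = dict(row)
            chars = d.get("characters", "")
            d["characters"] = [c for c in chars.split(";") if c] if chars else []
            d["teleport_in"] = d.get("teleport_in", "0") in ("1", "true", "True")
            shots.append(_shot_from_dict(d, row=i))
        movie = MovieAnnotation(movie_id=str(rows[0]["movie_id"]),
                                release_year=int(rows[0]["release_year"]),
                                genre=str(rows[0]["genre"]), shots=tuple(shots))
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")
    return movie.validate()


def write_movie(movie: MovieAnnotation, path: str | Path, format: str | None = None) -> None:
    """Write a validated movie with a deterministic field order.

    JSON output is canonical: same movie in, byte-identical file out.
    """
    movie.validate()
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        doc = {
            "movie_id": movie.movie_id,
            "release_year": movie.release_year,
            "genre": movie.genre,
            "shots": [_shot_to_dict(s) for s in movie.shots],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, ensure_ascii=False, indent=2)
            fh.write("\n")
    elif fmt == "csv":
        header = ("movie_id", "release_year", "genre") + _SHOT_FIELDS
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            for s in movie.shots:
                writer.writerow([
                    movie.movie_id, movie.release_year, movie.genre,
                    s.shot_index, repr(float(s.duration_s)), s.scale, s.location_id,
                    ";".join(sorted(s.characters)), s.transition_in, s.time_mark_in,
                    int(s.teleport_in), s.sound,
                ])
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")


def read_responses(path: str | Path) -> dict[str, ViewerResponseTable]:
    """Read a long-format viewer response CSV into per-movie tables."""
    with open(path, encoding="utf-8", newline="") as fh:
        rows = list(csv.DictReader(fh))
    per_movie: dict[str, dict[int, dict[str, int]]] = {}
    for i, row in enumerate(rows, start=1):
        try:
            mid = row["movie_id"]
            b = int(row["boundary_index"])
            vid = row["viewer_id"]
            resp = int(row["response"])
        except (KeyError, ValueError) as exc:
            raise AnnotationError(f"malformed response row: {exc}", row=i) from exc
        if resp not in (0, 1):
            raise AnnotationError("response must be 0 or 1", row=i, field="response")
        per_movie.setdefault(mid, {}).setdefault(b, {})[vid] = resp
    tables = {}
    for mid, bounds in per_movie.items():
        viewer_ids = sorted({vid for votes in bounds.values() for vid in votes})
        responses = {}
        for b, votes in sorted(bounds.items()):
            if set(votes) != set(viewer_ids):
                raise AnnotationError(
                    f"movie {mid}: boundary {b} missing responses for some viewers", row=b)
            responses[b] = tuple(votes[vid] for vid in viewer_ids)
        tables[mid] = ViewerResponseTable(mid, len(viewer_ids), responses).validate()
    return tables


def write_responses(tables: Iterable[ViewerResponseTable], path: str | Path) -> None:
    """Write per-movie response tables to a long-format CSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["movie_id", "boundary_index", "viewer_id", "response"])
        for table in tables:
            for b in sorted(table.responses):
                for v, resp in enumerate(table.responses[b], start=1):
                    writer.writerow([table.movie_id, b, f"v{v}", resp])
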