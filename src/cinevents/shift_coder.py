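"""Three-place narrative-shift coding at shot junctures.

A narrative shift is a change in one or more of three attributes across a
pair of adjacent shots: location (L), major characters (C), and time (T).
Each juncture therefore gets one of eight codes, rendered ``[L C T]``,
``[L C -]``, ..., ``[- - -]``, where ``[- - -]`` means no shift — the
within-scene juxtaposition of shots.

Coding rules
------------
* **Location** changes when the location label differs.
* **Characters** count only if they are *major*: appearing in strictly more
  than 10% of the movie's shots.  C is true when the major-character sets on
  the two sides differ, including present-to-absent transitions.  When both
  sides show no major characters the character code is null (C false).
* **Time** follows an explicit coder mark when present
  (``forward_ellipsis`` / ``backward`` force T; ``continuous`` forces no T).
  Otherwise it is inferred: when the location changes but the same non-empty
  set of major characters is shown, time necessarily changes too — the
  characters had to travel — unless the entry is marked as instantaneous
  transport (``teleport_in``).  At cross-cuts (location and characters both
  change, no mark) time is taken to run continuously, and with no location
  change and no mark time does not change.

Backward (flashback) and forward time shifts both code T=true; the direction
is kept in the derivation record only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from cinevents.annotations import AnnotationError, MovieAnnotation, ShotRecord

__all__ = [
    "SHIFT_LABELS",
    "ALL_LABELS",
    "NULL_LABEL",
    "ShiftCode",
    "BoundaryCode",
    "major_characters",
    "code_boundary",
    "code_movie",
    "shift_distribution",
    "MAJOR_CHARACTER_SHARE",
]

#: Appearance share (of a movie's shots) a character must strictly exceed
#: to count as major.
MAJOR_CHARACTER_SHARE = 0.10

NULL_LABEL = "[- - -]"

#: The seven shift types, in the conventional order.
SHIFT_LABELS = (
    "[L C T]", "[L C -]", "[L - T]", "[L - -]", "[- C T]", "[- C -]", "[- - T]",
)
ALL_LABELS = SHIFT_LABELS + (NULL_LABEL,)


def _render(L: bool, C: bool, T: bool) -> str:
    return "[{} {} {}]".format("L" if L else "-", "C" if C else "-", "T" if T else "-")


@dataclass(frozen=True)
class ShiftCode:
    """One (L, C, T) triple with its canonical label."""

    L: bool
    C: bool
    T: bool

    @property
    def label(self) -> str:
        return _render(self.L, self.C, self.T)

    @property
    def is_null(self) -> bool:
        return not (self.L or self.C or self.T)


@dataclass(frozen=True)
class BoundaryCode:
    """A shift code at one juncture, with a record of which time rule fired."""

    boundary_index: int
    code: ShiftCode
    derivation: str


def major_characters(movie: MovieAnnotation) -> frozenset[str]:
    """Characters appearing in strictly more than 10% of the movie's shots."""
    counts: Counter[str] = Counter()
    for shot in movie.shots:
        counts.update(shot.characters)
    threshold = MAJOR_CHARACTER_SHARE * movie.n_shots
    return frozenset(c for c, n in counts.items() if n > threshold)


def code_boundary(prev: ShotRecord, next: ShotRecord,
                  majors: frozenset[str]) -> tuple[ShiftCode, str]:
    """Code the juncture between two adjacent shots.

    Returns the :class:`ShiftCode` and a derivation string recording whether
    the time code came from an explicit mark or was inferred, and by which
    rule.
    """
    if next.time_mark_in not in ("auto", "continuous", "forward_ellipsis", "backward"):
        raise AnnotationError(f"unknown time mark {next.time_mark_in!r}",
                              row=next.shot_index, field="time_mark_in")

    L = prev.location_id != next.location_id

    m_prev = prev.characters & majors
    m_next = next.characters & majors
    if not m_prev and not m_next:
        C = False  # character code is null when no majors on either side
    else:
        C = m_prev != m_next

    mark = next.time_mark_in
    if mark == "forward_ellipsis":
        T, derivation = True, "explicit:forward"
    elif mark == "backward":
        T, derivation = True, "explicit:backward"
    elif mark == "continuous":
        T, derivation = False, "explicit:continuous"
    else:  # inferred
        if L and not C and m_prev and not next.teleport_in:
            # same non-empty major cast shown in a new place: they travelled
            T, derivation = True, "inferred:travel"
        elif L and not C and m_prev and next.teleport_in:
            T, derivation = False, "inferred:teleport"
        elif L and C:
            T, derivation = False, "inferred:crosscut-continuous"
        else:
            T, derivation = False, "inferred:no-cue"
    return ShiftCode(L, C, T), derivation


def code_movie(movie: MovieAnnotation) -> list[BoundaryCode]:
    """Code every juncture of a movie: exactly ``n_shots - 1`` codes."""
    movie.validate()
    majors = major_characters(movie)
    out = []
    for i in range(movie.n_shots - 1):
        code, derivation = code_boundary(movie.shots[i], movie.shots[i + 1], majors)
        out.append(BoundaryCode(boundary_index=i + 1, code=code, derivation=derivation))
    return out


def shift_distribution(codes: list[BoundaryCode],
                       mask: set[int] | None = None) -> dict[str, float]:
    """Percentage distribution over the seven shift types.

    Null (``[- - -]``) codes are excluded from the denominator.  ``mask``
    optionally restricts to a subset of boundary indices.
    """
    selected = [bc for bc in codes if mask is None or bc.boundary_index in mask]
    shifts = [bc.code.label for bc in selected if not bc.code.is_null]
    if not shifts:
        raise ValueError("no narrative shifts in selection: distribution undefined")
    counts = Counter(shifts)
    n = len(shifts)
    return {label: 100.0 * counts.get(label, 0) / n for label in SHIFT_LABELS}
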