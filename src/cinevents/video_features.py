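"""Per-shot low-level audiovisual measures from grayscale frame stacks.

Three classical cinemetric measures over a shot's frames (pixel values
0-255):

* **motion** — mean Pearson correlation between next-adjacent frames
  (pairs 1-3, 2-4, 3-5, ...); lower correlation means more motion, with
  1.0 for a perfectly static shot;
* **luminance** — the per-frame median pixel value, averaged over frames;
* **clutter** — the fraction of edge pixels (Sobel gradient magnitude above
  a fixed threshold), sampled on every tenth frame starting from the first
  and averaged.

Colour inputs are first converted to luminance with Rec.601 weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import sobel

__all__ = [
    "FrameStack",
    "shot_motion",
    "shot_luminance",
    "shot_clutter",
    "EDGE_THRESHOLD",
    "CLUTTER_FRAME_STRIDE",
]

logger = logging.getLogger(__name__)

#: Sobel gradient-magnitude threshold (on intensities rescaled to 0-1)
#: above which a pixel counts as an edge.  Fixed so results are
#: bit-reproducible.
EDGE_THRESHOLD = 0.1

#: Clutter is sampled on frames 1, 11, 21, ... (one in every ten).
CLUTTER_FRAME_STRIDE = 10

_REC601 = np.array([0.299, 0.587, 0.114])


def _to_gray(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3 and frame.shape[-1] == 3:
        frame = frame @ _REC601
    if frame.ndim != 2:
        raise ValueError(f"expected HxW or HxWx3 frame, got shape {frame.shape}")
    return frame


@dataclass(frozen=True)
class FrameStack:
    """An ordered stack of same-sized grayscale frames for one shot."""

    frames: tuple[np.ndarray, ...]
    frame_rate: float = 24.0

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("a frame stack needs at least one frame")
        gray = tuple(_to_gray(f) for f in self.frames)
        shapes = {g.shape for g in gray}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
        object.__setattr__(self, "frames", gray)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def shot_motion(stack: FrameStack) -> float:
    """Mean Pearson correlation of next-adjacent frame pairs (i, i+2).

    1.0 for a static shot; lower values mean more motion.  Zero-variance
    pairs are skipped (and logged).  Raises ``ValueError`` with fewer than
    three frames, where no next-adjacent pair exists.
    """
    if stack.n_frames < 3:
        raise ValueError("motion undefined: need at least 3 frames for (i, i+2) pairs")
    rs = []
    for i in range(stack.n_frames - 2):
        a = stack.frames[i].ravel()
        b = stack.frames[i + 2].ravel()
        sa, sb = a.std(), b.std()
        if sa == 0.0 or sb == 0.0:
            logger.info("skipping zero-variance frame pair (%d, %d)", i + 1, i + 3)
            continue
        rs.append(float(np.corrcoef(a, b)[0, 1]))
    if not rs:
        raise ValueError("motion undefined: all frame pairs have zero variance")
    return float(np.mean(rs))


def shot_luminance(stack: FrameStack) -> float:
    """Mean over frames of the per-frame median pixel value (0-255)."""
    return float(np.mean([np.median(f) for f in stack.frames]))


def shot_clutter(stack: FrameStack, threshold: float = EDGE_THRESHOLD) -> float:
    """Edge-pixel fraction, averaged over every tenth frame.

    Frames are rescaled to 0-1, filtered with a Sobel gradient-magnitude
    operator, and pixels above ``threshold`` count as edges.
    """
    fractions = []
    for frame in stack.frames[::CLUTTER_FRAME_STRIDE]:
        edges = sobel(frame / 255.0) > threshold
        fractions.append(edges.mean())
    return float(np.mean(fractions))
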