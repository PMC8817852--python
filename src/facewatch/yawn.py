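"""Yawn detection: inner-lip mouth aspect ratio and episode duration.

The mouth aspect ratio (MAR) is computed from inner-lip landmarks only:

    MAR = (|A1 - A2| + |B1 - B2|) / (2 |H1 - H2|),

where (A1, A2) and (B1, B2) are the two vertical inner-lip pairs and
(H1, H2) the inner mouth corners.  Using the inner lip makes the
closed-mouth MAR converge near 0 for all lip thicknesses, which is the
reason the outer-lip ratio is avoided.  A frame's mouth state is M = 1
(open) when MAR >= threshold (default 0.35).  Maximal open runs become
episodes; an episode's duration in frames (its COUNTER) classifies it as
ordinary opening (Y = 0, up to 25 frames — speech, snacking), yawn
(Y = 1, more than 25 up to 50) or deep yawn (Y = 2, more than 50), the
strongest single fatigue indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError, ValidationError

DEFAULT_MAR_THRESHOLD = 0.35
DEFAULT_YAWN_FRAMES = 25
DEFAULT_DEEP_YAWN_FRAMES = 50


@dataclass(frozen=True)
class MouthState:
    mar: float
    code: int  # 1 = open, 0 = closed


@dataclass(frozen=True)
class MouthEpisode:
    """One maximal mouth-open run, classified by its frame count."""

    start_frame: int
    end_frame: int
    yawn_class: int  # Y in {0, 1, 2}

    @property
    def counter(self) -> int:
        return self.end_frame - self.start_frame + 1


def compute_mar(vertical_a: np.ndarray, vertical_b: np.ndarray,
                horizontal: np.ndarray) -> float:
    """MAR from two vertical inner-lip pairs and the corner pair.

    Each argument is a (2, 2) array of pixel points.  Raises
    :class:`DegenerateGeometryError` on zero mouth width.
    """
    a = np.asarray(vertical_a, dtype=float)
    b = np.asarray(vertical_b, dtype=float)
    h = np.asarray(horizontal, dtype=float)
    for name, pair in (("vertical_a", a), ("vertical_b", b), ("horizontal", h)):
        if pair.shape != (2, 2):
            raise ValidationError(f"{name} must be a (2, 2) point pair")
    width = np.linalg.norm(h[0] - h[1])
    if width == 0.0:
        raise DegenerateGeometryError("zero mouth width")
    opening = np.linalg.norm(a[0] - a[1]) + np.linalg.norm(b[0] - b[1])
    return float(opening / (2.0 * width))


def classify_mouth(mar: float, threshold: float = DEFAULT_MAR_THRESHOLD) -> MouthState:
    """Binary mouth state: M = 1 iff MAR >= threshold (boundary open)."""
    if mar < 0:
        raise ValidationError(f"negative MAR {mar}")
    return MouthState(mar=float(mar), code=1 if mar >= threshold else 0)


def classify_yawn(counter: int, yawn_frames: int = DEFAULT_YAWN_FRAMES,
                  deep_yawn_frames: int = DEFAULT_DEEP_YAWN_FRAMES) -> int:
    """Episode class from its open-frame count.

    Y = 0 for counter <= yawn_frames, Y = 1 for
    yawn_frames < counter <= deep_yawn_frames, Y = 2 beyond.  The printed
    duration bands overlap at their endpoints; the boundaries here follow
    the prose reading ("more than 25 but less than 50 ... more than 50").
    """
    if counter < 0:
        raise ValidationError(f"negative counter {counter}")
    if counter <= yawn_frames:
        return 0
    if counter <= deep_yawn_frames:
        return 1
    return 2


def segment_mouth_episodes(
    states: Sequence[int],
    yawn_frames: int = DEFAULT_YAWN_FRAMES,
    deep_yawn_frames: int = DEFAULT_DEEP_YAWN_FRAMES,
    start_offset: int = 0,
) -> list[MouthEpisode]:
    """Segment a mouth-code sequence into classified open episodes.

    Episodes are the maximal runs of M = 1, returned in temporal order;
    they partition exactly the open frames.  ``start_offset`` shifts the
    reported frame indices (useful when the sequence is a slice of a
    longer stream).
    """
    s = np.asarray(states, dtype=int)
    if s.size and not np.isin(s, (0, 1)).all():
        raise ValidationError("mouth codes must be 0 or 1")
    episodes: list[MouthEpisode] = []
    padded = np.concatenate(([0], s, [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    for start, end in zip(starts, ends):
        length = int(end - start + 1)
        episodes.append(
            MouthEpisode(
                start_frame=int(start) + start_offset,
                end_frame=int(end) + start_offset,
                yawn_class=classify_yawn(length, yawn_frames, deep_yawn_frames),
            )
        )
    return episodes
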