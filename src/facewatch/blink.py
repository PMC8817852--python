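"""Blink detection: eye aspect ratio, per-frame eye state, blink counting.

The eye aspect ratio (EAR) of six eye landmarks P1..P6 is

    EAR = (|P2 - P6| + |P3 - P5|) / (2 |P1 - P4|),

the summed vertical lid distances over twice the horizontal corner
distance.  It is dimensionless and invariant under similarity transforms
of the six points; it collapses toward 0 as the lids close.  A frame's
eye state is E = 1 (open) when the EAR is at or above a threshold
(default 0.20) and E = 0 (closed) below it.  A blink is a maximal closed
run bracketed by open frames; the eye-closing rate of a window is the
fraction of its frames classified closed (the PERCLOS-style fatigue
proxy used by the per-minute alert rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import landmarks as lm
from .errors import DegenerateGeometryError, EmptyWindowError, ValidationError

DEFAULT_EAR_THRESHOLD = 0.20
DEFAULT_EAR_WEIGHT_LEFT = 0.5
DEFAULT_MIN_CLOSED_FRAMES = 1


@dataclass(frozen=True)
class EyeState:
    """Per-frame eye measurement: EAR value and binary open/closed code."""

    ear: float
    code: int  # 1 = open, 0 = closed


@dataclass(frozen=True)
class BlinkSummary:
    """Window aggregate of the eye channel."""

    blink_count: int
    closed_frames: int
    total_face_frames: int

    @property
    def closing_rate(self) -> float:
        if self.total_face_frames == 0:
            raise EmptyWindowError("no face frames in window")
        return self.closed_frames / self.total_face_frames


def compute_ear(points: np.ndarray) -> float:
    """EAR of six ordered eye points, shape (6, 2).

    Raises :class:`DegenerateGeometryError` when the corner distance
    |P1 - P4| is zero.
    """
    p = np.asarray(points, dtype=float)
    if p.shape != (6, 2):
        raise ValidationError(f"expected 6 eye points, got shape {p.shape}")
    horizontal = np.linalg.norm(p[0] - p[3])
    if horizontal == 0.0:
        raise DegenerateGeometryError("zero horizontal eye extent")
    vertical = np.linalg.norm(p[1] - p[5]) + np.linalg.norm(p[2] - p[4])
    return float(vertical / (2.0 * horizontal))


def frame_ear(frame: lm.LandmarkFrame, weight_left: float = DEFAULT_EAR_WEIGHT_LEFT,
              index_map: lm.LandmarkIndexMap = lm.DEFAULT_INDEX_MAP) -> float:
    """Weighted average of the left- and right-eye EAR of one frame.

    ``weight_left`` defaults to 0.5 (unweighted mean of the two eyes).
    """
    if not 0.0 <= weight_left <= 1.0:
        raise ValidationError(f"weight_left must be in [0, 1], got {weight_left}")
    ear_l = compute_ear(lm.eye_points(frame, "left", index_map))
    ear_r = compute_ear(lm.eye_points(frame, "right", index_map))
    return weight_left * ear_l + (1.0 - weight_left) * ear_r


def classify_eye(ear: float, threshold: float = DEFAULT_EAR_THRESHOLD) -> EyeState:
    """Binary eye state: E = 1 iff EAR >= threshold (boundary open)."""
    if ear < 0:
        raise ValidationError(f"negative EAR {ear}")
    return EyeState(ear=float(ear), code=1 if ear >= threshold else 0)


def count_blinks(states: Sequence[int],
                 min_closed_frames: int = DEFAULT_MIN_CLOSED_FRAMES) -> int:
    """Count blinks in a sequence of per-frame eye codes.

    A blink is a maximal run of 0 (closed) of length at least
    ``min_closed_frames`` that is both preceded and followed by a 1
    within the sequence (the open–close–open pattern); runs touching the
    sequence boundary are not counted.
    """
    s = np.asarray(states, dtype=int)
    if s.size and not np.isin(s, (0, 1)).all():
        raise ValidationError("eye codes must be 0 or 1")
    count = 0
    run = 0
    seen_open = False
    for code in s:
        if code == 1:
            if seen_open and run >= min_closed_frames:
                count += 1
            run = 0
            seen_open = True
        else:
            run += 1
    return count


def closing_rate(states: Sequence[int]) -> float:
    """Fraction of frames classified closed (code 0); in [0, 1]."""
    s = np.asarray(states, dtype=int)
    if s.size == 0:
        raise EmptyWindowError("closing_rate of empty window")
    if not np.isin(s, (0, 1)).all():
        raise ValidationError("eye codes must be 0 or 1")
    return float(np.mean(s == 0))
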