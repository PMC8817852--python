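"""Landmark data model, 68-point index conventions, and stream I/O.

The pipeline's input atom is a :class:`LandmarkFrame`: one video frame's
68 labeled 2D facial landmark points (iBUG / dlib numbering) plus a
face-presence flag.  Streams are JSON lines, one object per frame::

    {"frame": 0, "t": 0.0, "face": 1, "pts": [[x0, y0], ..., [x67, y67]]}

Frames with ``face == 0`` omit ``pts`` (or carry an empty list).  Pixel
coordinates use the convention of mainstream landmark detectors: origin
at the image top-left, y increasing downward.

Indexing is 0-based internally.  The field's customary 1-based numbers
(as printed on landmark diagrams) are each internal index plus one; the
inner-lip helpers below document both.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np

from .errors import AbsentFaceError, StreamFormatError, ValidationError

N_LANDMARKS = 68

#: 0-based landmark indices of the six left-eye points, in the standard
#: clockwise order starting at the outer corner (1-based 37..42).
LEFT_EYE = (36, 37, 38, 39, 40, 41)

#: 0-based indices of the six right-eye points (1-based 43..48).  Index 42
#: is the inner (nose-side) corner here; the aspect-ratio formula is
#: symmetric in the two corners so the same P1..P6 treatment applies.
RIGHT_EYE = (42, 43, 44, 45, 46, 47)

#: Inner-lip vertical pairs, 0-based: (61, 67) and (63, 65)
#: (1-based mouth points 62–68 and 64–66).
INNER_MOUTH_VERTICAL = ((61, 67), (63, 65))

#: Inner-lip horizontal (corner) pair, 0-based (60, 64) (1-based 61–65).
INNER_MOUTH_HORIZONTAL = (60, 64)

#: The 14 rigid pose points used for head-pose estimation, with role
#: labels.  "Nose base right" is landmark 35, the bilateral partner of 31.
POSE_POINT_LABELS = (
    ("brow_left_outer", 17),
    ("brow_left_inner", 21),
    ("brow_right_inner", 22),
    ("brow_right_outer", 26),
    ("eye_left_outer", 36),
    ("eye_left_inner", 39),
    ("eye_right_inner", 42),
    ("eye_right_outer", 45),
    ("nose_base_left", 31),
    ("nose_base_right", 35),
    ("mouth_corner_left", 48),
    ("mouth_corner_right", 54),
    ("lower_lip_center", 57),
    ("chin", 8),
)


@dataclass(frozen=True)
class LandmarkIndexMap:
    """Index conventions binding feature groups to the 68-point layout.

    All indices are 0-based and fixed at construction.  The default map
    follows the iBUG convention; ``pose_points`` may be overridden (e.g.
    to reproduce alternative readings of the nose-base pair).
    """

    left_eye: tuple[int, ...] = LEFT_EYE
    right_eye: tuple[int, ...] = RIGHT_EYE
    inner_mouth_vertical_pairs: tuple[tuple[int, int], ...] = INNER_MOUTH_VERTICAL
    inner_mouth_horizontal_pair: tuple[int, int] = INNER_MOUTH_HORIZONTAL
    pose_points: tuple[tuple[str, int], ...] = POSE_POINT_LABELS

    def __post_init__(self):
        mouth = tuple(
            i for pair in self.inner_mouth_vertical_pairs for i in pair
        ) + tuple(self.inner_mouth_horizontal_pair)
        groups = {
            "left_eye": self.left_eye,
            "right_eye": self.right_eye,
            "inner_mouth": mouth,
            "pose": tuple(i for _, i in self.pose_points),
        }
        for name, idx in groups.items():
            if any(not 0 <= int(i) < N_LANDMARKS for i in idx):
                raise ValidationError(f"{name} indices out of [0, 67]: {idx}")
            if len(set(idx)) != len(idx):
                raise ValidationError(f"{name} indices must be distinct")
        for eye, name in ((self.left_eye, "left_eye"), (self.right_eye, "right_eye")):
            if len(eye) != 6 or len(set(eye)) != 6:
                raise ValidationError(f"{name} must be 6 distinct indices")


DEFAULT_INDEX_MAP = LandmarkIndexMap()


@dataclass
class LandmarkFrame:
    """One video frame's landmarks.

    ``points`` is a (68, 2) float array when ``face_present`` is true and
    empty otherwise; coordinates are pixels.
    """

    frame_index: int
    timestamp: float
    face_present: bool
    points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.frame_index < 0:
            raise ValidationError(f"negative frame_index {self.frame_index}")
        if not math.isfinite(self.timestamp):
            raise ValidationError("non-finite timestamp")
        if self.face_present:
            if self.points.shape != (N_LANDMARKS, 2):
                raise ValidationError(
                    f"face frame needs {N_LANDMARKS} points, got {self.points.shape[0]}"
                )
            if not np.all(np.isfinite(self.points)):
                raise ValidationError("non-finite landmark coordinates")
        elif self.points.size:
            raise ValidationError("faceless frame carries points")


def _require_face(frame: LandmarkFrame) -> None:
    if not frame.face_present:
        raise AbsentFaceError(f"no face in frame {frame.frame_index}")


def eye_points(frame: LandmarkFrame, side: str,
               index_map: LandmarkIndexMap = DEFAULT_INDEX_MAP) -> np.ndarray:
    """Return the six eye points P1..P6 for ``side`` ('left' or 'right').

    P1 and P4 are the two eye corners (horizontal extent), P2/P3 the upper
    lid and P6/P5 the lower lid.  For the left eye P1 is the outer corner;
    for the right eye the corner roles are mirrored, which leaves the
    aspect ratio unchanged.
    """
    _require_face(frame)
    if side == "left":
        idx = index_map.left_eye
    elif side == "right":
        idx = index_map.right_eye
    else:
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    return frame.points[list(idx)]


def inner_mouth_points(
    frame: LandmarkFrame, index_map: LandmarkIndexMap = DEFAULT_INDEX_MAP
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return inner-lip point pairs: (vertical A, vertical B, horizontal).

    Each element is a (2, 2) array of pixel points.  0-based index pairs
    are (61, 67), (63, 65) vertical and (60, 64) horizontal — the mouth
    points printed as 62–68, 64–66 and 61–65 in 1-based diagrams.
    """
    _require_face(frame)
    (a, b) = index_map.inner_mouth_vertical_pairs
    h = index_map.inner_mouth_horizontal_pair
    pts = frame.points
    return pts[list(a)], pts[list(b)], pts[list(h)]


def pose_points(
    frame: LandmarkFrame, index_map: LandmarkIndexMap = DEFAULT_INDEX_MAP
) -> np.ndarray:
    """Return the 14 rigid pose points as a (14, 2) array in label order."""
    _require_face(frame)
    return frame.points[[i for _, i in index_map.pose_points]]


def _frame_to_obj(frame: LandmarkFrame) -> dict:
    obj = {
        "frame": int(frame.frame_index),
        "t": float(frame.timestamp),
        "face": 1 if frame.face_present else 0,
    }
    if frame.face_present:
        obj["pts"] = [[float(x), float(y)] for x, y in frame.points]
    return obj


def _obj_to_frame(obj: dict, line_number: int) -> LandmarkFrame:
    try:
        face = bool(obj["face"])
        pts = obj.get("pts", []) if face else []
        return LandmarkFrame(
            frame_index=int(obj["frame"]),
            timestamp=float(obj["t"]),
            face_present=face,
            points=np.asarray(pts, dtype=float).reshape(-1, 2),
        )
    except (KeyError, TypeError, ValueError, ValidationError) as exc:
        raise StreamFormatError(str(exc), line_number) from exc


def write_landmark_stream(frames: Iterable[LandmarkFrame], path_or_file) -> None:
    """Write frames as JSON lines to a path or an open text file."""
    if hasattr(path_or_file, "write"):
        fh: IO[str] = path_or_file
        for frame in frames:
            fh.write(json.dumps(_frame_to_obj(frame)) + "\n")
    else:
        with open(path_or_file, "w") as fh:
            write_landmark_stream(frames, fh)


def iter_landmark_stream(path_or_file) -> Iterator[LandmarkFrame]:
    """Yield frames lazily from a JSON-lines landmark stream.

    Raises :class:`StreamFormatError` (with the 1-based line number) on a
    malformed line and :class:`ValidationError` if frame indices are not
    strictly increasing or timestamps decrease.
    """
    if not hasattr(path_or_file, "read"):
        with open(path_or_file) as fh:
            yield from iter_landmark_stream(fh)
        return
    last_index = -1
    last_t = -math.inf
    for line_number, line in enumerate(path_or_file, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise StreamFormatError(f"invalid JSON: {exc}", line_number) from exc
        frame = _obj_to_frame(obj, line_number)
        if frame.frame_index <= last_index:
            raise ValidationError(
                f"line {line_number}: frame_index {frame.frame_index} "
                f"not greater than previous {last_index}"
            )
        if frame.timestamp < last_t:
            raise ValidationError(
                f"line {line_number}: timestamp decreased "
                f"({frame.timestamp} < {last_t})"
            )
        last_index, last_t = frame.frame_index, frame.timestamp
        yield frame


def read_landmark_stream(path_or_file) -> list[LandmarkFrame]:
    """Read a whole JSON-lines landmark stream into memory, in file order."""
    return list(iter_landmark_stream(path_or_file))
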