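"""Ground-truthed synthetic landmark streams.

The simulator scripts sessions of an online learner in front of a
webcam: blink episodes (transient EAR collapse), yawns (sustained
inner-lip MAR elevation of a scripted frame count), rigid head rotations
(the 3D face template rotated along smooth cosine ramps and re-projected
through the camera model), and face-loss gaps.  Isotropic Gaussian pixel
noise (seeded) is added last, so the noiseless geometry — from which all
ground truth is computed — is exact.

Ground truth is derived from the script with independent inline run
scans (not the pipeline's counting code), which makes end-to-end
agreement between :func:`facewatch.assessment.run_pipeline` and
:class:`GroundTruth` a genuine two-route check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from . import blink as _blink
from . import yawn as _yawn
from .config import PipelineConfig
from .errors import ScriptError
from .face3d import (
    FaceShape,
    apply_eye_closure,
    apply_mouth_opening,
    face_template_3d,
    pose_model_points,
)
from .headpose import euler_to_rotation, project
from .landmarks import LandmarkFrame, inner_mouth_points

EVENT_TYPES = ("blink", "yawn", "head_nod", "head_turn", "head_sway", "no_face")
_HEAD_AXIS = {"head_nod": 0, "head_turn": 1, "head_sway": 2}  # pitch, yaw, roll
_DEFAULT_MAGNITUDE = {"blink": 0.9, "yawn": 0.6,
                      "head_nod": 30.0, "head_turn": 30.0, "head_sway": 30.0}
#: extra frames of close/open ramp surrounding a scripted plateau
_RAMP = {"blink": 2, "yawn": 1}


@dataclass(frozen=True)
class ScenarioEvent:
    type: str
    start_s: float
    duration_s: float | None = None
    duration_frames: int | None = None
    magnitude: float | None = None

    def frames(self, fps: float) -> tuple[int, int]:
        """(start_frame, n_frames) of the event plateau."""
        start = int(round(self.start_s * fps))
        if self.duration_frames is not None:
            n = int(self.duration_frames)
        elif self.duration_s is not None:
            n = int(round(self.duration_s * fps))
        else:
            raise ScriptError(f"{self.type} event needs a duration")
        return start, n


@dataclass(frozen=True)
class ScenarioScript:
    """A scripted session: capture geometry, events, noise, seed."""

    duration_s: float
    events: tuple[ScenarioEvent, ...] = ()
    fps: float = 25.0
    noise_sd: float = 0.0
    seed: int = 0
    shape: FaceShape = field(default_factory=FaceShape)
    depth_mm: float = 600.0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class GroundTruth:
    """Per-frame true features and per-window expected aggregates."""

    face: np.ndarray          # (n,) bool
    ear: np.ndarray           # (n,) float, nan when no face
    mar: np.ndarray           # (n,)
    euler: np.ndarray         # (n, 3) scripted pitch/yaw/roll, deg
    eye_codes: np.ndarray     # (n,) int, -1 when no face
    mouth_codes: np.ndarray   # (n,) int, -1 when no face
    windows: list[dict]       # per-window aggregates + expected_alert


def _validate(script: ScenarioScript) -> None:
    spans: dict[str, list[tuple[int, int]]] = {}
    last_start = -np.inf
    for ev in script.events:
        if ev.type not in EVENT_TYPES:
            raise ScriptError(f"unknown event type {ev.type!r}")
        if ev.start_s < last_start:
            raise ScriptError("events must be temporally sorted")
        last_start = ev.start_s
        start, n = ev.frames(script.fps)
        if n <= 0:
            raise ScriptError(f"{ev.type} event with non-positive duration")
        if start < 0 or start + n > script.n_frames:
            raise ScriptError(f"{ev.type} event outside the session")
        mag = ev.magnitude
        if mag is None:
            mag = _DEFAULT_MAGNITUDE.get(ev.type)
        if ev.type == "blink" and not 0.0 < mag <= 1.0:
            raise ScriptError(f"blink depth outside (0, 1]: {mag}")
        if ev.type == "yawn" and not 0.35 <= mag <= 1.2:
            raise ScriptError(f"yawn opening outside [0.35, 1.2]: {mag}")
        if ev.type in _HEAD_AXIS and not 0.0 < mag <= 60.0:
            raise ScriptError(f"head magnitude outside (0, 60] deg: {mag}")
        pad = _RAMP.get(ev.type, 0)
        channel = _HEAD_AXIS.get(ev.type, ev.type)
        spans.setdefault(str(channel), []).append((start - pad, start + n + pad))
    # Same-channel overlap and no_face overlap with anything are invalid.
    def overlapping(a, b):
        return a[0] < b[1] and b[0] < a[1]

    for channel, chan_spans in spans.items():
        for i in range(1, len(chan_spans)):
            if overlapping(chan_spans[i - 1], chan_spans[i]):
                raise ScriptError(f"overlapping events on channel {channel}")
    for nf in spans.get("no_face", []):
        for channel, chan_spans in spans.items():
            if channel == "no_face":
                continue
            if any(overlapping(nf, s) for s in chan_spans):
                raise ScriptError("no_face overlaps a facial event")


def _profiles(script: ScenarioScript) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame (closure, mouth_mar_target, euler(n,3), face) arrays."""
    n = script.n_frames
    closure = np.zeros(n)
    mouth = np.zeros(n)
    euler = np.zeros((n, 3))
    face = np.ones(n, dtype=bool)
    for ev in script.events:
        start, length = ev.frames(script.fps)
        mag = ev.magnitude if ev.magnitude is not None else _DEFAULT_MAGNITUDE.get(ev.type)
        if ev.type == "blink":
            # 2-frame linear ramps around a full-depth plateau.
            for off, frac in ((-2, 1 / 3), (-1, 2 / 3)):
                if 0 <= start + off < n:
                    closure[start + off] = max(closure[start + off], frac * mag)
            closure[start:start + length] = mag
            for off, frac in ((0, 2 / 3), (1, 1 / 3)):
                i = start + length + off
                if 0 <= i < n:
                    closure[i] = max(closure[i], frac * mag)
        elif ev.type == "yawn":
            # 1-frame sub-threshold ramps; the plateau holds MAR = mag
            # for exactly `length` frames.
            if start - 1 >= 0:
                mouth[start - 1] = max(mouth[start - 1], 0.3 * mag)
            mouth[start:start + length] = mag
            if start + length < n:
                mouth[start + length] = max(mouth[start + length], 0.3 * mag)
        elif ev.type in _HEAD_AXIS:
            axis = _HEAD_AXIS[ev.type]
            ramp = max(2, min(12, length // 5))
            profile = np.full(length, mag, dtype=float)
            # Odd-denominator cosine ramp: no sample sits exactly at mag/2,
            # so a magnitude of twice the angular threshold can never place
            # a frame exactly on the in/out-of-range boundary.
            j = np.arange(ramp)
            up = mag * (1.0 - np.cos(np.pi * (2 * j + 1) / (2 * ramp + 1))) / 2.0
            profile[:ramp] = up
            profile[length - ramp:] = up[::-1]
            euler[start:start + length, axis] = profile
        elif ev.type == "no_face":
            face[start:start + length] = False
    return closure, mouth, euler, face


def neutral_template(
    shape: FaceShape = FaceShape(),
    config: PipelineConfig | None = None,
    depth_mm: float = 600.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Project the closed-mouth, open-eye face at neutral pose.

    Returns ``(points2d, model14, rotation, translation)`` where
    ``points2d`` is the (68, 2) pixel template and ``model14`` the
    matching rigid 3D pose model; by construction the template's pose
    points equal ``project(model14, rotation, translation)``.
    """
    config = config or PipelineConfig()
    template3d = face_template_3d(shape)
    rotation = np.eye(3)
    translation = np.array([0.0, 0.0, depth_mm])
    points2d = project(template3d, rotation, translation, config.intrinsics)
    return points2d, pose_model_points(template3d), rotation, translation


def render_stream(
    script: ScenarioScript, config: PipelineConfig | None = None
) -> tuple[list[LandmarkFrame], GroundTruth]:
    """Render a scenario script into a landmark stream plus ground truth.

    Identical script and seed give a bit-identical stream.  Ground-truth
    EAR/MAR are computed from the noiseless projected geometry; the
    Euler truth is the scripted trajectory itself.
    """
    config = config or PipelineConfig()
    _validate(script)
    n = script.n_frames
    closure, mouth, euler, face = _profiles(script)
    rng = np.random.default_rng(script.seed)
    translation = np.array([0.0, 0.0, script.depth_mm])
    base = face_template_3d(script.shape)

    frames: list[LandmarkFrame] = []
    ear_truth = np.full(n, np.nan)
    mar_truth = np.full(n, np.nan)
    eye_codes = np.full(n, -1, dtype=int)
    mouth_codes = np.full(n, -1, dtype=int)
    for t in range(n):
        timestamp = t / script.fps
        if not face[t]:
            frames.append(LandmarkFrame(t, timestamp, False))
            continue
        template = base
        if closure[t] > 0:
            template = apply_eye_closure(template, float(closure[t]), script.shape)
        if mouth[t] > 0:
            template = apply_mouth_opening(template, float(mouth[t]), script.shape)
        R = euler_to_rotation(*euler[t])
        pts = project(template, R, translation, config.intrinsics)
        clean = LandmarkFrame(t, timestamp, True, pts)
        ear_truth[t] = _blink.frame_ear(clean, config.ear_weight_left)
        a, b, h = inner_mouth_points(clean)
        mar_truth[t] = _yawn.compute_mar(a, b, h)
        eye_codes[t] = 1 if ear_truth[t] >= config.ear_threshold else 0
        mouth_codes[t] = 1 if mar_truth[t] >= config.mar_threshold else 0
        if script.noise_sd > 0:
            pts = pts + rng.normal(0.0, script.noise_sd, size=pts.shape)
            clean = LandmarkFrame(t, timestamp, True, pts)
        frames.append(clean)

    truth = GroundTruth(
        face=face, ear=ear_truth, mar=mar_truth, euler=euler,
        eye_codes=eye_codes, mouth_codes=mouth_codes,
        windows=_window_truth(face, eye_codes, mouth_codes, euler, config),
    )
    return frames, truth


def _scan_runs(codes: Sequence[int], value: int) -> list[tuple[int, int]]:
    """Maximal runs of ``value``: list of (start, length). Plain scan."""
    runs = []
    start = None
    for i, c in enumerate(codes):
        if c == value and start is None:
            start = i
        elif c != value and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(codes) - start))
    return runs


def _window_truth(face, eye_codes, mouth_codes, euler,
                  config: PipelineConfig) -> list[dict]:
    n = len(face)
    wf = config.window_frames
    n_windows = (n - 1) // wf + 1

    # Mouth episodes over the whole stream (no-face frames close a run),
    # attributed to the window where the episode ends.
    m = np.where(face, np.maximum(mouth_codes, 0), 0)
    yawns_by_window = {w: [0, 0] for w in range(n_windows)}
    for start, length in _scan_runs(m, 1):
        w = (start + length - 1) // wf
        if length > config.deep_yawn_frames:
            yawns_by_window[w][1] += 1
        elif length > config.yawn_frames:
            yawns_by_window[w][0] += 1

    windows = []
    thr = config.euler_threshold_deg
    for w in range(n_windows):
        sl = slice(w * wf, min((w + 1) * wf, n))
        face_w = face[sl]
        if not face_w.any():
            windows.append({
                "window": w, "closing_rate": None, "blink_count": 0,
                "yawn_count": 0, "deep_yawn_count": 0,
                "out_of_range_frames": {"pitch": 0, "yaw": 0, "roll": 0},
                "expected_alert": False,
            })
            continue
        eyes = eye_codes[sl][face_w]
        rate = float(np.mean(eyes == 0))
        blinks = 0
        for start, length in _scan_runs(eyes, 0):
            if start > 0 and start + length < len(eyes):
                blinks += 1
        yawn_count, deep_count = yawns_by_window[w]
        eul = euler[sl][face_w]
        oor = {
            c: int(np.sum(np.abs(eul[:, i]) > thr))
            for i, c in enumerate(("pitch", "yaw", "roll"))
        }
        alert = (
            rate > config.closing_rate_threshold
            or yawn_count >= config.yawn_alert_count
            or deep_count >= config.deep_yawn_alert_count
            or any(v > config.head_alert_frames for v in oor.values())
        )
        windows.append({
            "window": w, "closing_rate": rate, "blink_count": blinks,
            "yawn_count": yawn_count, "deep_yawn_count": deep_count,
            "out_of_range_frames": oor, "expected_alert": bool(alert),
        })
    return windows


# ---------------------------------------------------------------------------
# Script generation and (de)serialization
# ---------------------------------------------------------------------------

def random_script(seed: int, duration_s: float = 24.0, fps: float = 25.0,
                  noise_sd: float = 0.0) -> ScenarioScript:
    """Draw a random but valid scenario script.

    Events are placed sequentially with random gaps; types, magnitudes
    and durations span the physically plausible ranges (blink depth
    0.7–0.95, yawn opening 0.45–0.8 held 10–70 frames, head excursions
    18–40 degrees held 1–8 s, occasional face loss).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    events: list[ScenarioEvent] = []
    frame = 5
    while frame < n - 30:
        kind = rng.choice(EVENT_TYPES, p=[0.35, 0.2, 0.13, 0.13, 0.13, 0.06])
        if kind == "blink":
            length = int(rng.integers(2, 8))
            mag = float(rng.uniform(0.7, 0.95))
        elif kind == "yawn":
            length = int(rng.integers(10, 71))
            mag = float(rng.uniform(0.45, 0.8))
        elif kind == "no_face":
            length = int(rng.integers(5, 40))
            mag = None
        else:
            length = int(rng.integers(int(fps), int(8 * fps)))
            mag = float(rng.uniform(18.0, 40.0))
        if frame + length + 4 >= n:
            break
        events.append(ScenarioEvent(
            type=str(kind), start_s=frame / fps,
            duration_frames=length, magnitude=mag,
        ))
        frame += length + 4 + int(rng.integers(2, 40))
    return ScenarioScript(duration_s=duration_s, fps=fps, noise_sd=noise_sd,
                          seed=seed, events=tuple(events))


def load_script(path) -> ScenarioScript:
    """Load a scenario script from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    events = tuple(
        ScenarioEvent(**ev) for ev in data.pop("events", [])
    )
    shape = FaceShape(**data.pop("shape", {}))
    return ScenarioScript(events=events, shape=shape, **data)


def save_script(script: ScenarioScript, path) -> None:
    """Write a scenario script as YAML."""
    data = {
        "duration_s": script.duration_s, "fps": script.fps,
        "noise_sd": script.noise_sd, "seed": script.seed,
        "depth_mm": script.depth_mm,
        "shape": {"width_scale": script.shape.width_scale,
                  "lip_thickness": script.shape.lip_thickness,
                  "eye_openness": script.shape.eye_openness},
        "events": [
            {k: v for k, v in {
                "type": ev.type, "start_s": ev.start_s,
                "duration_s": ev.duration_s,
                "duration_frames": ev.duration_frames,
                "magnitude": ev.magnitude,
            }.items() if v is not None}
            for ev in script.events
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
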