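"""Per-minute fusion of the eye, mouth and head channels into alerts.

The alert rule evaluates each fixed window (default one minute of video):
an alert is raised when the eye-closing rate exceeds 0.2, or the window
contains two yawns (or one deep yawn), or any head Euler channel is out
of its ±15° band for more than 120 frames in the window.  Windows where
no face was ever detected carry a NO_FACE reason and never alert.

Two code paths apply the same rule: :func:`assess_window` aggregates
per-frame features first, while :func:`evaluate_record` takes already
tabulated aggregates (one row of a detection-results table).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import blink, yawn
from .config import PipelineConfig
from .errors import EmptyWindowError, ValidationError
from .headpose import (
    HeadState,
    classify_head,
    classify_head_event,
    solve_pose,
    update_head_counters,
)
from .face3d import pose_model_points
from .landmarks import LandmarkFrame, inner_mouth_points, pose_points

ALERT_REASONS = ("CLOSING_RATE", "YAWN", "DEEP_YAWN",
                 "HEAD_PITCH", "HEAD_YAW", "HEAD_ROLL", "NO_FACE")

CHANNELS = ("pitch", "yaw", "roll")
_CHANNEL_REASON = {"pitch": "HEAD_PITCH", "yaw": "HEAD_YAW", "roll": "HEAD_ROLL"}


@dataclass
class FrameFeatures:
    """Per-frame measurements; feature fields are None without a face."""

    frame_index: int
    face_present: bool
    ear: float | None = None
    eye_code: int | None = None
    mar: float | None = None
    mouth_code: int | None = None
    euler: tuple[float, float, float] | None = None
    head_code: int | None = None
    head_event: int | None = None
    out_of_range: tuple[bool, bool, bool] = (False, False, False)


@dataclass
class WindowAssessment:
    """One window's aggregates and alert decision (one report row)."""

    window_index: int
    face_coverage: float
    eye_closing_rate: float | None
    blink_count: int
    yawn_count: int
    deep_yawn_count: int
    out_of_range_frames: dict[str, int]
    representative_euler: dict[str, float | None]
    alert: bool
    reasons: list[str] = field(default_factory=list)


def _alert_from_aggregates(
    face: bool,
    closing_rate: float | None,
    yawn_count: int,
    deep_yawn_count: int,
    out_of_range_frames: dict[str, int],
    config: PipelineConfig,
) -> tuple[bool, list[str]]:
    if not face:
        return False, ["NO_FACE"]
    reasons = []
    if closing_rate is not None and closing_rate > config.closing_rate_threshold:
        reasons.append("CLOSING_RATE")
    if yawn_count >= config.yawn_alert_count:
        reasons.append("YAWN")
    if deep_yawn_count >= config.deep_yawn_alert_count:
        reasons.append("DEEP_YAWN")
    for channel in CHANNELS:
        if out_of_range_frames.get(channel, 0) > config.head_alert_frames:
            reasons.append(_CHANNEL_REASON[channel])
    return bool(reasons), reasons


def assess_window(
    features: Sequence[FrameFeatures],
    config: PipelineConfig | None = None,
    window_index: int = 0,
    episodes: Sequence[yawn.MouthEpisode] | None = None,
) -> WindowAssessment:
    """Aggregate one window of per-frame features and apply the alert rule.

    ``episodes`` may carry mouth episodes already segmented over the full
    stream (so runs that straddle window boundaries keep their global
    counter); when omitted, episodes are segmented from the window's own
    mouth codes.
    """
    config = config or PipelineConfig()
    if len(features) == 0:
        raise EmptyWindowError("empty feature window")
    face_frames = [f for f in features if f.face_present]
    coverage = len(face_frames) / len(features)
    if not face_frames:
        return WindowAssessment(
            window_index=window_index, face_coverage=0.0, eye_closing_rate=None,
            blink_count=0, yawn_count=0, deep_yawn_count=0,
            out_of_range_frames={c: 0 for c in CHANNELS},
            representative_euler={c: None for c in CHANNELS},
            alert=False, reasons=["NO_FACE"],
        )

    eye_codes = [f.eye_code for f in face_frames]
    rate = blink.closing_rate(eye_codes)
    blinks = blink.count_blinks(eye_codes, config.min_closed_frames)

    if episodes is None:
        episodes = yawn.segment_mouth_episodes(
            [f.mouth_code for f in face_frames],
            config.yawn_frames, config.deep_yawn_frames,
        )
    yawn_count = sum(1 for e in episodes if e.yawn_class == 1)
    deep_count = sum(1 for e in episodes if e.yawn_class == 2)

    oor = {c: 0 for c in CHANNELS}
    rep: dict[str, float | None] = {c: None for c in CHANNELS}
    for f in face_frames:
        for i, c in enumerate(CHANNELS):
            if f.out_of_range[i]:
                oor[c] += 1
            value = f.euler[i]
            if rep[c] is None or abs(value) > abs(rep[c]):
                rep[c] = value

    alert, reasons = _alert_from_aggregates(
        True, rate, yawn_count, deep_count, oor, config
    )
    return WindowAssessment(
        window_index=window_index, face_coverage=coverage,
        eye_closing_rate=rate, blink_count=blinks,
        yawn_count=yawn_count, deep_yawn_count=deep_count,
        out_of_range_frames=oor, representative_euler=rep,
        alert=alert, reasons=reasons,
    )


_RECORD_FIELDS = ("face", "eye_closing_rate", "yawn", "deep_yawn",
                  "yaw_frames", "pitch_frames", "roll_frames")


def evaluate_record(record: dict, config: PipelineConfig | None = None) -> tuple[bool, list[str]]:
    """Apply the alert rule to tabulated window aggregates.

    ``record`` must carry ``face`` (0/1) and, when a face was present,
    ``eye_closing_rate``, ``yawn``, ``deep_yawn`` and per-channel
    ``{pitch,yaw,roll}_frames`` out-of-range totals (angle values such as
    ``pitch`` may be present but do not enter the rule).  Returns
    ``(alert, reasons)``.
    """
    config = config or PipelineConfig()
    if "face" not in record:
        raise ValidationError("record missing 'face'")
    if not record["face"]:
        return _alert_from_aggregates(False, None, 0, 0, {}, config)
    missing = [k for k in _RECORD_FIELDS if k not in record]
    if missing:
        raise ValidationError(f"record missing fields: {missing}")
    return _alert_from_aggregates(
        True,
        float(record["eye_closing_rate"]),
        int(record["yawn"]),
        int(record["deep_yawn"]),
        {c: int(record[f"{c}_frames"]) for c in CHANNELS},
        config,
    )


def run_pipeline(
    frames: Iterable[LandmarkFrame],
    config: PipelineConfig | None = None,
    face_model: np.ndarray | None = None,
) -> tuple[list[WindowAssessment], list[FrameFeatures]]:
    """Run the full per-frame feature extraction and windowed assessment.

    Per face frame: the two-eye EAR and its open/closed code, the
    inner-lip MAR and its code, the head pose solved from the 14 rigid
    landmarks (warm-started from the previous frame) with its Euler
    angles, per-channel out-of-range flags and consecutive counters.
    Frames are then grouped into fixed windows of ``config.window_frames``
    by frame index and assessed.  Mouth episodes are segmented over the
    whole stream and attributed to the window where they end, so a run
    straddling a boundary keeps its full counter.  Deterministic given
    the stream and configuration.
    """
    config = config or PipelineConfig()
    model = pose_model_points() if face_model is None else np.asarray(face_model)

    features: list[FrameFeatures] = []
    head_state = HeadState()
    previous_pose = None
    for frame in frames:
        if not frame.face_present:
            head_state = HeadState()  # face loss breaks consecutive runs
            previous_pose = None
            features.append(FrameFeatures(frame.frame_index, False))
            continue
        ear = blink.frame_ear(frame, config.ear_weight_left)
        eye_code = blink.classify_eye(ear, config.ear_threshold).code
        a, b, h = inner_mouth_points(frame)
        mar = yawn.compute_mar(a, b, h)
        mouth_code = yawn.classify_mouth(mar, config.mar_threshold).code
        pose = solve_pose(model, pose_points(frame), config.intrinsics,
                          initial=previous_pose)
        previous_pose = pose
        euler = pose.euler
        thr = config.euler_threshold_deg
        out = tuple(not (-thr <= a_ <= thr) for a_ in euler)
        head_state = update_head_counters(euler, head_state, thr)
        features.append(FrameFeatures(
            frame_index=frame.frame_index, face_present=True,
            ear=ear, eye_code=eye_code, mar=mar, mouth_code=mouth_code,
            euler=euler, head_code=classify_head(euler, thr),
            head_event=classify_head_event(head_state, config.head_frame_threshold),
            out_of_range=out,
        ))

    if not features:
        raise EmptyWindowError("empty landmark stream")

    # Global mouth-episode segmentation (face-absent frames close a run).
    mouth_codes = [f.mouth_code if f.face_present else 0 for f in features]
    episodes = yawn.segment_mouth_episodes(
        mouth_codes, config.yawn_frames, config.deep_yawn_frames
    )

    wf = config.window_frames
    windows: list[WindowAssessment] = []
    n_windows = (features[-1].frame_index // wf) + 1
    by_window: dict[int, list[FrameFeatures]] = {}
    for f in features:
        by_window.setdefault(f.frame_index // wf, []).append(f)
    for w in range(n_windows):
        group = by_window.get(w)
        if not group:
            continue
        window_episodes = [
            e for e in episodes
            if features[e.end_frame].frame_index // wf == w
        ]
        windows.append(assess_window(group, config, window_index=w,
                                     episodes=window_episodes))
    return windows, features


def windows_to_frame(windows: Sequence[WindowAssessment]) -> pd.DataFrame:
    """Tabulate window assessments as a report DataFrame (one row each)."""
    rows = []
    for w in windows:
        rows.append({
            "window": w.window_index,
            "face": round(w.face_coverage, 3),
            "eye_closing_rate": None if w.eye_closing_rate is None
            else round(w.eye_closing_rate, 4),
            "blink": w.blink_count,
            "yawn": w.yawn_count,
            "deep_yawn": w.deep_yawn_count,
            "yaw": w.representative_euler["yaw"],
            "yaw_frames": w.out_of_range_frames["yaw"],
            "pitch": w.representative_euler["pitch"],
            "pitch_frames": w.out_of_range_frames["pitch"],
            "roll": w.representative_euler["roll"],
            "roll_frames": w.out_of_range_frames["roll"],
            "alert": "Y" if w.alert else "N",
            "reasons": "|".join(w.reasons),
        })
    return pd.DataFrame(rows)


def features_to_frame(features: Sequence[FrameFeatures]) -> pd.DataFrame:
    """Tabulate the per-frame feature log."""
    rows = []
    for f in features:
        row = {"frame": f.frame_index, "face": int(f.face_present),
               "ear": f.ear, "E": f.eye_code, "mar": f.mar, "M": f.mouth_code,
               "H": f.head_code, "P": f.head_event}
        for i, c in enumerate(CHANNELS):
            row[c] = None if f.euler is None else f.euler[i]
        rows.append(row)
    return pd.DataFrame(rows)
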