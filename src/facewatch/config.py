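"""Pipeline configuration: thresholds, camera intrinsics, window geometry.

All frame-count thresholds are stored in frames (the scale the method's
duration rules are defined on); ``fps`` only converts the window length
and event timings.  Every value can be overridden from a YAML mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ValidationError
from .headpose import CameraIntrinsics


@dataclass
class PipelineConfig:
    # Eye channel
    ear_threshold: float = 0.20
    ear_weight_left: float = 0.5
    min_closed_frames: int = 1
    # Mouth channel
    mar_threshold: float = 0.35
    yawn_frames: int = 25
    deep_yawn_frames: int = 50
    # Head channel
    euler_threshold_deg: float = 15.0
    head_frame_threshold: int = 60
    # Window / fusion rule
    fps: float = 25.0
    window_seconds: float = 60.0
    closing_rate_threshold: float = 0.20
    yawn_alert_count: int = 2
    deep_yawn_alert_count: int = 1
    head_alert_frames: int = 120
    # Camera
    intrinsics: CameraIntrinsics = field(
        default_factory=CameraIntrinsics.default
    )

    def __post_init__(self):
        if self.fps <= 0 or self.window_seconds <= 0:
            raise ValidationError("fps and window_seconds must be positive")
        if self.yawn_frames > self.deep_yawn_frames:
            raise ValidationError("yawn_frames must not exceed deep_yawn_frames")

    @property
    def window_frames(self) -> int:
        return int(round(self.fps * self.window_seconds))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        intr = data.pop("intrinsics", None)
        cfg = cls(**data) if intr is None else cls(
            **data, intrinsics=CameraIntrinsics(**intr)
        )
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)
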