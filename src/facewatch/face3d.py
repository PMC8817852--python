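"""Generic anthropometric 3D face geometry for pose solving and simulation.

Coordinates are millimetres in a head-attached frame: origin near the
nose root, x to the image right, y downward (matching the pixel
convention), z pointing away from the camera at neutral pose (deeper
anatomy — ears, jaw angle — has larger z; the nose tip has the smallest).
At neutral pose the head frame is axis-aligned with the camera frame.

The module builds a full 68-landmark 3D template parametrized by a few
shape knobs (face width, outer-lip thickness, lid opening), from which
the 14-point rigid model used by the pose solver is extracted.  The
numbers are a stylized average adult face: the pose pipeline is
self-consistent against whatever model is used, so the exact values
matter only when interpreting poses of real faces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import POSE_POINT_LABELS
from .errors import ValidationError


@dataclass(frozen=True)
class FaceShape:
    """Shape knobs for the 68-point template.

    width_scale: lateral scaling of the whole face (1.0 = average).
    lip_thickness: extra outer-lip flesh in mm (0 = thin, ~4 = thick);
        affects outer-lip points only, by construction.
    eye_openness: lid half-separation in mm at neutral (EAR ~ openness/12.5).
    """

    width_scale: float = 1.0
    lip_thickness: float = 0.0
    eye_openness: float = 3.5

    def __post_init__(self):
        if not 0.5 <= self.width_scale <= 1.5:
            raise ValidationError("width_scale outside [0.5, 1.5]")
        if not 0.0 <= self.lip_thickness <= 8.0:
            raise ValidationError("lip_thickness outside [0, 8] mm")
        if not 1.0 <= self.eye_openness <= 6.0:
            raise ValidationError("eye_openness outside [1, 6] mm")


#: Inner-lip vertical half-separation at rest (mm); keeps the closed-mouth
#: inner MAR near 0.03 for every shape variant.
_INNER_LIP_GAP = 1.5
_EYE_Y = -25.0
_INNER_UPPER_Y = 54.0
_INNER_LOWER_Y = _INNER_UPPER_Y + _INNER_LIP_GAP


def face_template_3d(shape: FaceShape = FaceShape()) -> np.ndarray:
    """Return the (68, 3) landmark template in mm for a face shape."""
    pts = np.zeros((68, 3))
    # Jaw line 0..16: half-ellipse from ear to ear through the chin.
    phi = np.pi * np.arange(17) / 16.0
    pts[0:17, 0] = -78.0 * np.cos(phi)
    pts[0:17, 1] = -20.0 + 118.0 * np.sin(phi)
    pts[0:17, 2] = 55.0 * np.cos(phi) ** 2
    # Brows 17..21 (image left) and 22..26 (image right).
    bx = np.array([-55.0, -45.0, -35.0, -25.0, -15.0])
    by = -48.0 - 6.0 * np.sin(np.pi * np.arange(5) / 4.0)
    pts[17:22] = np.c_[bx, by, np.full(5, 15.0)]
    pts[22:27] = np.c_[-bx[::-1], by[::-1], np.full(5, 15.0)]
    # Nose bridge 27..30 and base 31..35.
    pts[27:31] = [(0, -35, 5), (0, -22, -3), (0, -9, -11), (0, 4, -18)]
    pts[31:36] = [(-16, 16, 0), (-8, 18, -4), (0, 20, -6), (8, 18, -4), (16, 16, 0)]
    # Eyes 36..41 (left) and 42..47 (right).
    e = shape.eye_openness
    pts[36:42] = [(-45, _EYE_Y, 8), (-38, _EYE_Y - e, 5), (-27, _EYE_Y - e, 5),
                  (-20, _EYE_Y, 4), (-27, _EYE_Y + e, 5), (-38, _EYE_Y + e, 5)]
    pts[42:48] = [(20, _EYE_Y, 4), (27, _EYE_Y - e, 5), (38, _EYE_Y - e, 5),
                  (45, _EYE_Y, 8), (38, _EYE_Y + e, 5), (27, _EYE_Y + e, 5)]
    # Outer lips 48..59; lip_thickness pushes the outer vermilion outward.
    t = shape.lip_thickness
    pts[48:60] = [(-28, 55, 5), (-18, 49 - t, 1), (-8, 46 - t, -1),
                  (0, 45 - t, -2), (8, 46 - t, -1), (18, 49 - t, 1),
                  (28, 55, 5), (18, 61 + t, 1), (8, 64 + t, -1),
                  (0, 65 + t, -1), (-8, 64 + t, -1), (-18, 61 + t, 1)]
    # Inner lips 60..67: a nearly-closed slit regardless of lip thickness.
    pts[60:68] = [(-22, 55, 2), (-10, _INNER_UPPER_Y, 0), (0, _INNER_UPPER_Y, 0),
                  (10, _INNER_UPPER_Y, 0), (22, 55, 2), (10, _INNER_LOWER_Y, 0),
                  (0, _INNER_LOWER_Y, 0), (-10, _INNER_LOWER_Y, 0)]
    pts[:, 0] *= shape.width_scale
    return pts


def pose_model_points(template: np.ndarray | None = None) -> np.ndarray:
    """Extract the (14, 3) rigid pose model from a 68-point 3D template.

    The subset is bilaterally symmetric and non-coplanar, as the pose
    solver requires.
    """
    if template is None:
        template = face_template_3d()
    template = np.asarray(template, dtype=float)
    if template.shape != (68, 3):
        raise ValidationError(f"expected (68, 3) template, got {template.shape}")
    return template[[i for _, i in POSE_POINT_LABELS]].copy()


def apply_eye_closure(template: np.ndarray, closure: float,
                      shape: FaceShape = FaceShape()) -> np.ndarray:
    """Move the eight lid points toward the lid line by ``closure`` in [0, 1].

    closure = 0 leaves the template unchanged; closure = 1 collapses both
    vertical lid separations (EAR -> 0).  None of the moved points belong
    to the rigid pose subset, so head-pose estimates are unaffected.
    """
    if not 0.0 <= closure <= 1.0:
        raise ValidationError(f"closure outside [0, 1]: {closure}")
    out = template.copy()
    e = shape.eye_openness * (1.0 - closure)
    for upper, lower in ((37, 41), (38, 40), (43, 47), (44, 46)):
        out[upper, 1] = _EYE_Y - e
        out[lower, 1] = _EYE_Y + e
    return out


def apply_mouth_opening(template: np.ndarray, mar: float,
                        shape: FaceShape = FaceShape()) -> np.ndarray:
    """Separate the inner-lip verticals so the model-plane MAR equals ``mar``.

    Only the six inner vertical lip points (61–63 upper, 65–67 lower) move;
    the mouth corners and the outer lip — which include rigid pose points —
    stay fixed, so simulated yawns do not perturb head-pose estimates.
    """
    if not 0.0 <= mar <= 1.5:
        raise ValidationError(f"mouth mar target outside [0, 1.5]: {mar}")
    out = template.copy()
    width = abs(out[64, 0] - out[60, 0])
    gap = max(mar * width, _INNER_LIP_GAP)
    lower_y = _INNER_UPPER_Y + gap
    for i in (65, 66, 67):
        out[i, 1] = lower_y
    return out
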