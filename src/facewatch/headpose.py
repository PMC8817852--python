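"""Head-pose estimation and the head state machine.

Camera model
------------
A model point ``U`` (mm, head frame) maps to the camera frame by the
rigid transform ``X = R U + T``, is normalized by depth to the image
center plane ``(u, v) = (X/Z, Y/Z)``, optionally distorted radially
(k1, k2, k3) and tangentially (p1, p2), and finally mapped to pixels by
the intrinsic matrix ``[[fx, 0, cx], [0, fy, cy], [0, 0, 1]]``.

Pose solving
------------
:func:`solve_pose` recovers ``(R, T)`` from >= 6 2D–3D correspondences:
a direct linear transform (DLT) on undistorted normalized coordinates
gives the linear initialization, then Levenberg-damped Gauss–Newton
iterations minimize the sum of squared pixel reprojection residuals
``J = Σ (x̂_i − x_i)² + (ŷ_i − y_i)²``.

Orientation conventions
-----------------------
Euler angles are degrees with pitch about x (nod), yaw about y (turn),
roll about z (sway), composed as ``R = Rz(roll) · Ry(yaw) · Rx(pitch)``.
The decomposition is singular at |yaw| = 90°, where roll is set to 0.
A head is "normal" (H = 1) when all three angles lie within
±euler_threshold (default 15°).  Per-channel counters track consecutive
out-of-range frames; sustained pitch or roll excursions (> 60 frames)
signal fatigue (P = 1), sustained yaw signals sight deviation (P = 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    BehindCameraError,
    ConvergenceError,
    SingularConfigurationError,
    ValidationError,
)

DEFAULT_EULER_THRESHOLD_DEG = 15.0
DEFAULT_HEAD_FRAME_THRESHOLD = 60


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics (pixels) plus radial/tangential distortion."""

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValidationError("focal lengths must be positive")

    @classmethod
    def default(cls, image_width: int = 640, image_height: int = 480) -> "CameraIntrinsics":
        """Uncalibrated-webcam approximation: f = image width, c = center."""
        return cls(fx=float(image_width), fy=float(image_width),
                   cx=image_width / 2.0, cy=image_height / 2.0)

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.fx, 0.0, self.cx],
                         [0.0, self.fy, self.cy],
                         [0.0, 0.0, 1.0]])

    @property
    def has_distortion(self) -> bool:
        return any((self.k1, self.k2, self.k3, self.p1, self.p2))


def _check_rotation(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValidationError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol) or not np.isclose(
        np.linalg.det(R), 1.0, atol=tol
    ):
        raise ValidationError("matrix is not a proper rotation")
    return R


@dataclass(frozen=True)
class Pose:
    """Rigid head pose: rotation matrix, translation (mm), derived angles."""

    rotation: np.ndarray
    translation: np.ndarray
    reprojection_rms: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @property
    def euler(self) -> tuple[float, float, float]:
        """(pitch, yaw, roll) in degrees."""
        return rotation_to_euler(self.rotation)

    @property
    def rotation_vector(self) -> np.ndarray:
        return rotation_to_rodrigues(self.rotation)


def distort(uv: np.ndarray, intrinsics: CameraIntrinsics) -> np.ndarray:
    """Apply radial + tangential distortion to normalized coordinates."""
    uv = np.atleast_2d(np.asarray(uv, dtype=float))
    u, v = uv[:, 0], uv[:, 1]
    r2 = u * u + v * v
    radial = 1.0 + intrinsics.k1 * r2 + intrinsics.k2 * r2**2 + intrinsics.k3 * r2**3
    du = 2.0 * intrinsics.p1 * u * v + intrinsics.p2 * (r2 + 2.0 * u * u)
    dv = 2.0 * intrinsics.p2 * u * v + intrinsics.p1 * (r2 + 2.0 * v * v)
    return np.c_[u * radial + du, v * radial + dv]


def undistort(uv: np.ndarray, intrinsics: CameraIntrinsics,
              iterations: int = 8) -> np.ndarray:
    """Invert :func:`distort` by fixed-point iteration (exact when k=p=0)."""
    uv = np.atleast_2d(np.asarray(uv, dtype=float))
    if not intrinsics.has_distortion:
        return uv.copy()
    guess = uv.copy()
    for _ in range(iterations):
        err = distort(guess, intrinsics) - guess
        guess = uv - err
    return guess


def project(points3d: np.ndarray, rotation: np.ndarray, translation: np.ndarray,
            intrinsics: CameraIntrinsics) -> np.ndarray:
    """Project (n, 3) model points to (n, 2) pixel coordinates.

    Raises :class:`BehindCameraError` if any transformed point has
    non-positive depth.
    """
    pts = np.atleast_2d(np.asarray(points3d, dtype=float))
    cam = pts @ np.asarray(rotation, dtype=float).T + np.asarray(
        translation, dtype=float
    ).reshape(3)
    z = cam[:, 2]
    if np.any(z <= 0):
        raise BehindCameraError("model point at non-positive camera depth")
    uv = cam[:, :2] / z[:, None]
    uv = distort(uv, intrinsics)
    return np.c_[intrinsics.fx * uv[:, 0] + intrinsics.cx,
                 intrinsics.fy * uv[:, 1] + intrinsics.cy]


# ---------------------------------------------------------------------------
# Rotation parameterizations
# ---------------------------------------------------------------------------

def rodrigues_to_rotation(vec: np.ndarray) -> np.ndarray:
    """Axis-angle rotation vector (radians) to rotation matrix."""
    v = np.asarray(vec, dtype=float).reshape(3)
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite rotation vector")
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        K = _skew(v)
        return np.eye(3) + K  # first-order term; exact at theta = 0
    axis = v / theta
    K = _skew(axis)
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def rotation_to_rodrigues(R: np.ndarray) -> np.ndarray:
    """Rotation matrix to axis-angle vector with angle in [0, pi].

    Goes through a unit quaternion (largest-component extraction), which
    is numerically stable at all angles including half turns.
    """
    R = _check_rotation(R)
    # Shepperd-style quaternion extraction: pick the largest of
    # (w, x, y, z) from the diagonal to avoid catastrophic cancellation.
    tr = np.trace(R)
    candidates = np.array([tr, R[0, 0], R[1, 1], R[2, 2]])
    k = int(np.argmax(candidates))
    if k == 0:
        s = np.sqrt(1.0 + tr) * 2.0
        q = np.array([s / 4.0, (R[2, 1] - R[1, 2]) / s,
                      (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s])
    else:
        i = k - 1
        j, l = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(1.0 + R[i, i] - R[j, j] - R[l, l]) * 2.0
        q = np.empty(4)
        q[0] = (R[l, j] - R[j, l]) / s
        q[1 + i] = s / 4.0
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + l] = (R[l, i] + R[i, l]) / s
    if q[0] < 0:
        q = -q
    q /= np.linalg.norm(q)
    vec_norm = np.linalg.norm(q[1:])
    theta = 2.0 * np.arctan2(vec_norm, q[0])
    if vec_norm < 1e-300:
        return np.zeros(3)
    return theta * q[1:] / vec_norm


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def euler_to_rotation(pitch: float, yaw: float, roll: float) -> np.ndarray:
    """Compose R = Rz(roll) @ Ry(yaw) @ Rx(pitch), angles in degrees."""
    a, b, c = np.deg2rad([pitch, yaw, roll])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    Rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def rotation_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    """Decompose R = Rz(roll) @ Ry(yaw) @ Rx(pitch); degrees.

    Pitch and roll lie in (-180, 180], yaw in [-90, 90].  At the gimbal
    singularity |yaw| = 90 roll is set to 0 and pitch absorbs the
    remaining rotation, deterministically.
    """
    R = _check_rotation(R)
    s = np.clip(-R[2, 0], -1.0, 1.0)
    yaw = np.arcsin(s)
    if 1.0 - abs(s) < 1e-12:
        sign = 1.0 if s > 0 else -1.0
        pitch = np.arctan2(sign * R[0, 1], sign * R[0, 2])
        roll = 0.0
    else:
        pitch = np.arctan2(R[2, 1], R[2, 2])
        roll = np.arctan2(R[1, 0], R[0, 0])
    return tuple(float(np.rad2deg(v)) for v in (pitch, yaw, roll))


# ---------------------------------------------------------------------------
# PnP: DLT initialization + damped Gauss-Newton refinement
# ---------------------------------------------------------------------------

def _dlt_pose(object_points: np.ndarray, normalized: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear [R|T] estimate from undistorted normalized image coordinates."""
    n = object_points.shape[0]
    A = np.zeros((2 * n, 12))
    X, x = object_points, normalized
    Xh = np.c_[X, np.ones(n)]
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -x[:, [0]] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -x[:, [1]] * Xh
    _, s, vt = np.linalg.svd(A)
    if s[-2] < 1e-10 * s[0]:
        raise SingularConfigurationError("degenerate correspondence geometry")
    M = vt[-1].reshape(3, 4)
    Rr = M[:, :3]
    if np.linalg.det(Rr) < 0:
        M, Rr = -M, -Rr
    scale = 3.0 / np.sum(np.linalg.svd(Rr, compute_uv=False))
    U, _, Vt = np.linalg.svd(Rr)
    R = U @ np.diag([1.0, 1.0, np.linalg.det(U @ Vt)]) @ Vt
    t = scale * M[:, 3]
    if t[2] <= 0:
        # Cheirality failure (object behind camera): fall back to a
        # neutral initialization at a depth matched to the point spread;
        # the damped Gauss-Newton refinement recovers from there.
        extent3d = np.ptp(X, axis=0).max()
        extent2d = max(np.ptp(x, axis=0).max(), 1e-6)
        R = np.eye(3)
        t = np.array([0.0, 0.0, extent3d / extent2d])
    return R, t


def _residuals(params: np.ndarray, object_points: np.ndarray,
               image_points: np.ndarray, intrinsics: CameraIntrinsics) -> np.ndarray:
    R = rodrigues_to_rotation(params[:3])
    predicted = project(object_points, R, params[3:], intrinsics)
    return (predicted - image_points).ravel()


def solve_pose(object_points: np.ndarray, image_points: np.ndarray,
               intrinsics: CameraIntrinsics, initial: Pose | None = None,
               max_iterations: int = 100, tol: float = 1e-12) -> Pose:
    """Recover the rigid pose from n >= 6 2D–3D correspondences.

    DLT on undistorted normalized coordinates initializes the pose
    (skipped when ``initial`` is given, e.g. the previous video frame's
    pose); Levenberg-damped Gauss–Newton then minimizes the summed
    squared pixel reprojection residuals.  The returned rotation is
    orthonormal and ``reprojection_rms`` carries the final RMS residual
    in pixels.
    """
    obj = np.atleast_2d(np.asarray(object_points, dtype=float))
    img = np.atleast_2d(np.asarray(image_points, dtype=float))
    if obj.shape[0] != img.shape[0] or obj.shape[1] != 3 or img.shape[1] != 2:
        raise ValidationError("need matching (n,3) object and (n,2) image points")
    n = obj.shape[0]
    if n < 6:
        raise SingularConfigurationError(f"need >= 6 correspondences, got {n}")
    if np.linalg.matrix_rank(obj - obj.mean(axis=0), tol=1e-8) < 2:
        raise SingularConfigurationError("collinear object points")

    if initial is None:
        normalized = undistort(
            np.c_[(img[:, 0] - intrinsics.cx) / intrinsics.fx,
                  (img[:, 1] - intrinsics.cy) / intrinsics.fy],
            intrinsics,
        )
        R0, t0 = _dlt_pose(obj, normalized)
        params = np.concatenate([rotation_to_rodrigues(R0), t0])
    else:
        params = np.concatenate(
            [initial.rotation_vector, initial.translation]
        )

    r = _residuals(params, obj, img, intrinsics)
    cost = float(r @ r)
    lam = 1e-3
    eps = 1e-6
    converged = False
    for _ in range(max_iterations):
        # Numeric central-difference Jacobian (2n x 6).
        J = np.empty((r.size, 6))
        for k in range(6):
            dp = np.zeros(6)
            dp[k] = eps
            J[:, k] = (
                _residuals(params + dp, obj, img, intrinsics)
                - _residuals(params - dp, obj, img, intrinsics)
            ) / (2.0 * eps)
        JtJ = J.T @ J
        g = J.T @ r
        step_accepted = False
        for _ in range(20):
            try:
                delta = np.linalg.solve(JtJ + lam * np.diag(np.diag(JtJ) + 1e-12), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            trial = params + delta
            try:
                r_trial = _residuals(trial, obj, img, intrinsics)
            except BehindCameraError:
                lam *= 10.0
                continue
            cost_trial = float(r_trial @ r_trial)
            if cost_trial < cost:
                params, r = trial, r_trial
                improvement = cost - cost_trial
                cost = cost_trial
                lam = max(lam / 10.0, 1e-12)
                step_accepted = True
                if cost < 1e-20 or improvement <= tol * max(cost, 1.0):
                    converged = True
                break
            lam *= 10.0
        if not step_accepted:
            converged = True  # damping exhausted: at a (local) minimum
        if converged:
            break
    if not converged:
        raise ConvergenceError(
            f"pose refinement did not converge (cost {cost:.3e})",
            residual=float(np.sqrt(cost / n)),
        )
    R = rodrigues_to_rotation(params[:3])
    return Pose(rotation=R, translation=params[3:],
                reprojection_rms=float(np.sqrt(cost / n)))


# ---------------------------------------------------------------------------
# Head state machine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeadState:
    """Per-frame head normality code and consecutive out-of-range counters."""

    code: int = 1  # H: 1 = normal, 0 = abnormal
    pcounter: int = 0
    ycounter: int = 0
    rcounter: int = 0


def classify_head(euler: tuple[float, float, float],
                  threshold: float = DEFAULT_EULER_THRESHOLD_DEG) -> int:
    """H = 1 iff pitch, yaw and roll all lie in [-threshold, +threshold]."""
    pitch, yaw, roll = euler
    if not all(np.isfinite([pitch, yaw, roll])):
        raise ValidationError("non-finite Euler angles")
    inside = all(-threshold <= a <= threshold for a in (pitch, yaw, roll))
    return 1 if inside else 0


def update_head_counters(euler: tuple[float, float, float], state: HeadState,
                         threshold: float = DEFAULT_EULER_THRESHOLD_DEG) -> HeadState:
    """Advance the per-channel counters by one frame.

    A channel's counter increments while that angle is outside
    [-threshold, +threshold] and resets to 0 the frame it re-enters.
    """
    pitch, yaw, roll = euler
    out = [not (-threshold <= a <= threshold) for a in (pitch, yaw, roll)]
    return HeadState(
        code=0 if any(out) else 1,
        pcounter=state.pcounter + 1 if out[0] else 0,
        ycounter=state.ycounter + 1 if out[1] else 0,
        rcounter=state.rcounter + 1 if out[2] else 0,
    )


def head_event_flags(state: HeadState,
                     frame_threshold: int = DEFAULT_HEAD_FRAME_THRESHOLD) -> set[str]:
    """All currently triggered head events (may be both)."""
    flags = set()
    if state.pcounter > frame_threshold or state.rcounter > frame_threshold:
        flags.add("FATIGUE")
    if state.ycounter > frame_threshold:
        flags.add("SIGHT_DEVIATION")
    return flags


def classify_head_event(state: HeadState,
                        frame_threshold: int = DEFAULT_HEAD_FRAME_THRESHOLD) -> int:
    """Scalar head event code P.

    P = 1 (fatigue) when the pitch or roll counter exceeds the frame
    threshold, P = 2 (sight deviation) when the yaw counter does, else 0.
    When both conditions hold the safety-critical fatigue code wins;
    :func:`head_event_flags` exposes the full set.
    """
    if min(state.pcounter, state.ycounter, state.rcounter) < 0:
        raise ValidationError("negative counters")
    flags = head_event_flags(state, frame_threshold)
    if "FATIGUE" in flags:
        return 1
    if "SIGHT_DEVIATION" in flags:
        return 2
    return 0
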