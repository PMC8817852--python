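import numpy as np
import pytest

from facewatch import LandmarkFrame, neutral_template
from facewatch.face3d import pose_model_points
from facewatch.headpose import CameraIntrinsics


@pytest.fixture(scope="session")
def intrinsics():
    return CameraIntrinsics.default()


@pytest.fixture(scope="session")
def pose_model():
    return pose_model_points()


@pytest.fixture(scope="session")
def neutral_frame():
    """Default-shape neutral face as a LandmarkFrame."""
    points2d, _, _, _ = neutral_template()
    return LandmarkFrame(frame_index=0, timestamp=0.0, face_present=True,
                         points=points2d)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_similarity(rng):
    """A random rotation + uniform scale + translation of the plane."""
    theta = rng.uniform(0, 2 * np.pi)
    scale = rng.uniform(0.1, 10.0)
    c, s = np.cos(theta), np.sin(theta)
    A = scale * np.array([[c, -s], [s, c]])
    b = rng.uniform(-100, 100, 2)
    return lambda pts: pts @ A.T + b


# The ten published window records used to validate the alert rule:
# (face, eye_closing_rate, yawn, deep_yawn, yaw, yaw_frames, pitch,
#  pitch_frames, roll, roll_frames, expected alert flag).
DETECTION_RECORDS = [
    dict(face=1, eye_closing_rate=0.23, yawn=0, deep_yawn=0, yaw=-8.19,
         yaw_frames=6, pitch=-3.48, pitch_frames=0, roll=-1.67,
         roll_frames=0, expected="Y"),
    dict(face=1, eye_closing_rate=0.03, yawn=0, deep_yawn=1, yaw=2.00,
         yaw_frames=0, pitch=1.78, pitch_frames=0, roll=0.73,
         roll_frames=0, expected="Y"),
    dict(face=0, expected="N"),
    dict(face=1, eye_closing_rate=0.11, yawn=2, deep_yawn=0, yaw=19.13,
         yaw_frames=7, pitch=-6.32, pitch_frames=0, roll=4.05,
         roll_frames=0, expected="Y"),
    dict(face=1, eye_closing_rate=0.06, yawn=1, deep_yawn=0, yaw=32.60,
         yaw_frames=206, pitch=-19.13, pitch_frames=35, roll=1.70,
         roll_frames=0, expected="Y"),
    dict(face=1, eye_closing_rate=0.09, yawn=0, deep_yawn=0, yaw=6.57,
         yaw_frames=0, pitch=-3.43, pitch_frames=0, roll=-3.70,
         roll_frames=0, expected="N"),
    dict(face=1, eye_closing_rate=0.32, yawn=0, deep_yawn=2, yaw=18.49,
         yaw_frames=17, pitch=-13.46, pitch_frames=0, roll=-20.95,
         roll_frames=72, expected="Y"),
    dict(face=1, eye_closing_rate=0.14, yawn=1, deep_yawn=0, yaw=4.36,
         yaw_frames=0, pitch=-20.31, pitch_frames=137, roll=-0.59,
         roll_frames=0, expected="Y"),
    dict(face=1, eye_closing_rate=0.16, yawn=1, deep_yawn=0, yaw=23.72,
         yaw_frames=12, pitch=-9.98, pitch_frames=0, roll=8.31,
         roll_frames=0, expected="N"),
    dict(face=1, eye_closing_rate=0.05, yawn=0, deep_yawn=0, yaw=2.95,
         yaw_frames=0, pitch=-5.93, pitch_frames=0, roll=-23.53,
         roll_frames=139, expected="Y"),
]


def reference_pnp(object_points, image_points, intrinsics):
    """Independent PnP oracle: scipy least-squares with scipy rotations.

    Deliberately shares no code with facewatch.headpose.solve_pose: the
    rotation is parameterized through scipy.spatial.transform.Rotation,
    the optimizer is scipy's Levenberg-Marquardt least_squares, and the
    initialization is a coarse multi-start grid of orientations at a
    depth set by the point spread (the reprojection objective has local
    minima for shallow 3D models, so a single frontal start is not
    enough).  Distortion-free intrinsics only.
    """
    from itertools import product

    from scipy.optimize import least_squares
    from scipy.spatial.transform import Rotation

    K = intrinsics.matrix
    obj = np.asarray(object_points, float)
    img = np.asarray(image_points, float)

    def residual(p):
        R = Rotation.from_rotvec(p[:3]).as_matrix()
        cam = obj @ R.T + p[3:]
        z = cam[:, 2]
        if np.any(z <= 1e-9):
            return np.full(2 * len(obj), 1e6)
        proj = cam @ K.T
        proj = proj[:, :2] / proj[:, [2]]
        return (proj - img).ravel()

    norm = np.c_[(img[:, 0] - intrinsics.cx) / intrinsics.fx,
                 (img[:, 1] - intrinsics.cy) / intrinsics.fy]
    spread2d = max(np.ptp(norm, axis=0).max(), 1e-9)
    depth0 = np.ptp(obj, axis=0).max() / spread2d

    best = None
    grid = (-40.0, 0.0, 40.0)
    for pitch, yaw, roll in product(grid, grid, grid):
        rotvec0 = Rotation.from_euler(
            "ZYX", [roll, yaw, pitch], degrees=True).as_rotvec()
        x0 = np.r_[rotvec0, 0.0, 0.0, depth0]
        sol = least_squares(residual, x0, method="lm", xtol=1e-15,
                            ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-16:
            break
    R = Rotation.from_rotvec(best.x[:3]).as_matrix()
    return R, best.x[3:]
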