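# Methods

## Scope and data model

The pipeline operates purely on 68-point 2D facial-landmark streams
(iBUG/dlib numbering; pixels, origin top-left, y down). Face and
landmark *detection* from images is out of scope: any detector — or the
built-in simulator — can feed the stream. Streams are JSON lines
(`{"frame", "t", "face", "pts"}`), chosen for append-ability from a
live producer; indices are 0-based internally with the customary
1-based numbers documented alongside.

## Eye channel

EAR = (‖P2−P6‖+‖P3−P5‖)/(2‖P1−P4‖) per eye; the frame value is the
convex combination `w·EAR_left + (1−w)·EAR_right` with `ear_weight_left
= 0.5` by default — no asymmetry between the eyes is assumed, and the
weight is exposed for users who have one (e.g. ptosis). E = 1 iff
EAR ≥ `ear_threshold` (0.20), boundary on the open side. A blink is a
maximal closed run bracketed by open frames with length ≥
`min_closed_frames` (default 1; real detectors may want 2 for noise
rejection — the simulator needs no debounce). Closing rate is computed
over face-present frames only; faceless frames are reported as lost
coverage instead of polluting either side of the ratio. No head-pose
correction is applied to EAR: the ratio is similarity-invariant, and
projected eye width shrinks with |yaw| roughly as cos(yaw), which
*raises* EAR under rotation — a conservative direction for closure
detection but a known bias at extreme poses.

## Mouth channel

MAR uses inner-lip landmarks only — vertical pairs (62,68), (64,66) and
corner pair (61,65), 1-based — because the inner aperture is nearly
zero for a closed mouth regardless of vermilion thickness, which makes
the 0.35 threshold portable across faces; the outer-lip ratio is not
implemented as a detection path. Open runs of the M code become
episodes; `COUNTER` is the run length in frames and maps to
Y = 0 (≤ 25), 1 (25, 50], 2 (> 50). The printed duration bands overlap
at their endpoints; the boundary assignment here follows the prose
reading ("more than 25 but less than 50 … more than 50"), and both
`yawn_frames` and `deep_yawn_frames` are configuration keys. A
deep-yawn episode counts only as a deep yawn in window tallies, never
additionally as a yawn. Episodes are segmented over the whole stream,
so a run straddling a window boundary keeps its global counter and is
attributed to the window where it ends. The frame thresholds implicitly
assume ~25 fps capture; they are deliberately kept in frames (set
`yawn_frames = round(seconds × fps)` for other rates).

## Head channel

**Camera model.** `X = R·U + T`, normalization `(u,v) = (X/Z, Y/Z)`,
radial (k1,k2,k3) and tangential (p1,p2) distortion, then the pinhole
intrinsics. Default intrinsics are the standard uncalibrated-webcam
approximation fx = fy = image width, principal point at the image
center, zero distortion; all overridable.

**3D model.** `face3d` ships a stylized average adult 68-point template
(mm; origin near the nose root, x right, y down, z away from the
camera at neutral) from which the 14 rigid pose points are extracted:
brow corners 17/21/22/26, eye corners 36/39/42/45, nose base 31/35,
mouth corners 48/54, lower-lip center 57, chin 8 (0-based). The
customary pose-point listing names "nose lower right 39", which
collides with the eye corner already listed; 35 — the bilateral partner
of 31 — is used, and the map is configurable. The solver is
self-consistent against whatever model is supplied, so the template's
exact millimetres matter only when interpreting real faces.

**PnP.** DLT on undistorted normalized coordinates (SVD null vector,
rotation orthonormalized by projection, cheirality checked with a
neutral fallback) initializes; Levenberg-damped Gauss–Newton on the
summed squared pixel reprojection residual refines, with a numeric
central-difference Jacobian (ε = 1e−6), damping adaptation ×10/÷10,
convergence when the cost improvement falls below 1e−12 relative or
the cost below 1e−20, cap 100 iterations (non-convergence raises,
carrying the last RMS). In the streaming pipeline each frame is
warm-started from the previous frame's pose, which typically converges
in a couple of iterations (~1–3 ms/frame on one core). Noise-free
synthetic round trips recover Euler angles to < 0.01° with reprojection
RMS < 1e−6 px; under 1 px isotropic landmark noise the median
worst-channel Euler error measured over 100 random poses (±30°) is
≈ 1.5°, regression-bounded at 3°.

**Orientation.** R = R_z(roll)·R_y(yaw)·R_x(pitch), degrees; pitch ≈
nod, yaw ≈ turn, roll ≈ sway. The decomposition's singularity is at
|yaw| = 90° (the middle angle), far outside the ±15° operating band;
there roll is set to 0 deterministically. Rodrigues conversion goes
through a largest-component quaternion extraction, stable at all
angles.

**State machine.** H = 1 requires *all three* angles within
±`euler_threshold_deg` (15°). (A disjunctive reading of the normality
rule would make H = 1 almost always and would be inconsistent with
per-channel counters, so the conjunctive form is used.) Each channel's
counter counts consecutive out-of-range frames and resets on re-entry;
P = 1 (fatigue) when the pitch or roll counter exceeds
`head_frame_threshold` (60), P = 2 (sight deviation) for yaw. When both
fire, both flags are reported and the scalar code prefers the
safety-critical P = 1.

## Fusion rule

Per window (default 60 s × 25 fps = 1500 frames): alert iff
closing_rate > 0.2, or yawn count ≥ 2, or deep-yawn count ≥ 1, or any
channel's **total** out-of-range frames in the window > 120. The
120-frame clause is a windowed total (not necessarily consecutive) —
the per-event 60-frame consecutive counters remain a separate per-frame
signal, and both quantities are logged. The 60-frame event threshold
and the 120-frame alert threshold are independent configuration keys.
Boundaries are strict exactly where the rule says "greater than": a
closing rate of exactly 0.2 or exactly 120 out-of-range frames does not
alert. Windows with zero face coverage yield no alert with reason
`NO_FACE` — an aggregate monitor for absence is a policy decision left
to the caller. `assess_window` (from per-frame features) and
`evaluate_record` (from tabulated aggregates) share one clause
implementation and are cross-tested against each other.

## Simulator

The simulator renders scripted sessions from the same geometric model
the pipeline inverts: per frame, the 68-point 3D template is deformed
(lid closure, inner-lip opening — never touching the 14 rigid pose
points, so facial events cannot bias pose estimates), rotated by the
scripted Euler trajectory, projected through the configured camera,
and only then perturbed by seeded isotropic Gaussian pixel noise
(`noise_sd`, default 0; 0.5 px in robustness checks). Ground truth —
per-frame EAR/MAR from the noiseless projection, the scripted Euler
trajectory, and per-window aggregates with the expected alert — is
derived with independent inline run scans, not the pipeline's counting
code, so zero-noise end-to-end agreement is a genuine two-route check.

Event kinematics: blinks use 2-frame linear ramps around a full-depth
plateau (default depth 0.9, EAR ≈ 0.03); yawns use 1-frame
sub-threshold ramps so the MAR plateau lasts exactly the scripted frame
count; head events use an odd-denominator cosine ramp whose samples can
never land exactly on the angular threshold, keeping out-of-range frame
counts exact. Same-channel events may not overlap, and face loss may
not overlap facial events.

What the simulator does *not* emulate: detector-specific landmark error
structure (correlated jitter, occlusion dropout, identity-dependent
bias), illumination effects, non-rigid expression, or real facial
anthropometry beyond the stylized template. Passing tests therefore
demonstrate the correctness of the feature computation, state machines
and fusion logic — not detector robustness on real video.

## Default parameters

| key | default | meaning |
| --- | --- | --- |
| `ear_threshold` | 0.20 | eye open/closed EAR boundary |
| `ear_weight_left` | 0.5 | left-eye weight in the two-eye average |
| `min_closed_frames` | 1 | debounce for counted blinks |
| `mar_threshold` | 0.35 | mouth open/closed MAR boundary |
| `yawn_frames` / `deep_yawn_frames` | 25 / 50 | episode duration bands (frames) |
| `euler_threshold_deg` | 15 | head normality band (deg, all channels) |
| `head_frame_threshold` | 60 | consecutive frames for a head event |
| `fps` / `window_seconds` | 25 / 60 | window = 1500 frames |
| `closing_rate_threshold` | 0.20 | alert clause (strict >) |
| `yawn_alert_count` / `deep_yawn_alert_count` | 2 / 1 | alert clauses |
| `head_alert_frames` | 120 | windowed out-of-range total (strict >) |
| intrinsics | fx=fy=640, c=(320,240), no distortion | uncalibrated webcam |

## Problem sizes in the test suite

The end-to-end corpus uses 50 random 24-second sessions (600 frames
each, window = session) — long enough to contain multi-second head
excursions and the full yawn-duration range while keeping the whole
suite under two minutes on one core. The published one-minute window
is exercised directly in the README example and the windowing tests.

## Known limitations

- EAR/MAR thresholds are operating points for roughly frontal faces;
  no pose normalization of the ratios is attempted.
- The PnP solver assumes a rigid face; strong expressions move the
  mouth-corner and chin landmarks and bias pitch estimates on real
  faces (the simulator deliberately avoids this by construction).
- The DLT initialization degrades for near-planar landmark
  configurations; the shipped model is non-coplanar but shallow, which
  is why the refinement stage, not the DLT, carries the accuracy.
- Frame-count thresholds do not adapt to the capture rate.
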