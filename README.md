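# facewatch

Learning-state and fatigue assessment from 68-point facial-landmark
streams.

Online learners (and drivers, and radiologists on night shift) signal
fatigue and lost attention through their faces: long eyelid closures,
yawns, and sustained head turns away from the screen. `facewatch`
implements a monitoring pipeline that consumes a stream of 68-point 2D
facial landmarks — from any face-alignment detector, or from the
built-in ground-truthed simulator — and fuses three channels into a
per-minute alert decision:

- **Blink / eye closure.** The eye aspect ratio of the six eye
  landmarks P1..P6,

  EAR = (‖P2−P6‖ + ‖P3−P5‖) / (2 ‖P1−P4‖),

  averaged over both eyes. A frame is *closed* (E = 0) when EAR < 0.20.
  The **eye-closing rate** of a window — the fraction of frames closed,
  a PERCLOS-style statistic — is the fatigue proxy; blinks
  (open–close–open runs) are counted as well.
- **Yawn.** The mouth aspect ratio computed from **inner-lip**
  landmarks only (vertical pairs 62–68 and 64–66, corners 61–65 in the
  usual 1-based numbering), so that a closed mouth scores near 0 for
  every lip thickness. The mouth is *open* (M = 1) when MAR ≥ 0.35;
  maximal open runs of length `COUNTER` are classed Y = 0 (ordinary
  opening, ≤ 25 frames), Y = 1 (yawn, 25–50) or Y = 2 (deep yawn, > 50).
- **Head pose.** 14 rigid landmarks (brow and eye corners, nose base,
  mouth corners, lower lip, chin) are matched to a 3D anthropometric
  face model through a pinhole-plus-distortion camera; the rotation and
  translation are solved by DLT initialization and damped Gauss–Newton
  refinement of the reprojection error (a PnP solve), and decomposed as
  R = R_z(roll)·R_y(yaw)·R_x(pitch). The head is *normal* (H = 1) when
  all three angles lie in ±15°; per-channel counters of consecutive
  out-of-range frames raise a fatigue event (P = 1) for sustained pitch
  or roll (> 60 frames) and a sight-deviation event (P = 2) for
  sustained yaw.

**Alert rule** (per one-minute window, 25 fps ⇒ 1500 frames): alert iff

    closing_rate > 0.2   OR   yawns ≥ 2   OR   deep yawns ≥ 1
    OR   any Euler channel out of ±15° for > 120 frames in the window.

All thresholds are configuration keys; the defaults above are the
method's published operating point.

## Worked example

Script a one-minute session with one blink, one 60-frame yawn and a
6-second 30° head turn, render it to landmarks, and assess it:

```python
from facewatch import (PipelineConfig, ScenarioEvent, ScenarioScript,
                       render_stream, run_pipeline)
from facewatch.assessment import windows_to_frame

script = ScenarioScript(duration_s=60.0, events=(
    ScenarioEvent("blink", start_s=5.0, duration_frames=4),
    ScenarioEvent("yawn", start_s=12.0, duration_frames=60, magnitude=0.6),
    ScenarioEvent("head_turn", start_s=30.0, duration_s=6.0, magnitude=30.0),
))
cfg = PipelineConfig()
frames, truth = render_stream(script, cfg)
windows, features = run_pipeline(frames, cfg)
print(windows_to_frame(windows).to_string(index=False))
```

```
 window  face  eye_closing_rate  blink  yawn  deep_yawn  yaw  yaw_frames        pitch  pitch_frames          roll  roll_frames alert            reasons
      0   1.0            0.0053      1     0          1 30.0         138 8.266636e-11             0 -1.067968e-11            0     Y DEEP_YAWN|HEAD_YAW
```

The 60-frame mouth opening exceeds the 50-frame deep-yawn band, and the
head turn keeps yaw beyond ±15° for 138 > 120 frames, so the window
alerts for both reasons; the measured yaw at maximum excursion is the
scripted 30°, and the closing rate 0.0053 reflects the single 4-frame
blink (8 closed frames of 1500). `truth.windows[0]` carries the
simulator's independently derived expectation of exactly these numbers.

The same pipeline is scriptable from the shell:

```
facewatch simulate --script scenario.yaml --out stream.jsonl --truth truth.json
facewatch assess --landmarks stream.jsonl --out report.csv --frames-log frames.csv
facewatch evaluate --record '{"face":1,"eye_closing_rate":0.23,"yawn":0,
    "deep_yawn":0,"yaw_frames":0,"pitch_frames":0,"roll_frames":0}'
```

## Layout

| module | contents |
| --- | --- |
| `facewatch.landmarks` | frame/stream data model, index conventions, JSON-lines I/O |
| `facewatch.blink` | EAR, eye state, blink counting, closing rate |
| `facewatch.yawn` | inner-lip MAR, mouth state, episode segmentation and classes |
| `facewatch.headpose` | camera model, PnP solver, Rodrigues/Euler, head state machine |
| `facewatch.assessment` | windowed aggregation, alert rule, full pipeline, reports |
| `facewatch.simulator` | 3D-face-based scenario renderer with exact ground truth |
| `facewatch.face3d` | parametric 68-point anthropometric 3D face template |
| `facewatch.cli` | `facewatch simulate / assess / evaluate` |

See `docs/methods.md` for the model details, conventions, parameter
defaults and known limitations.
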