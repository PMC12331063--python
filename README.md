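# dualskel

Dual-camera 3-D human-skeleton fusion for markerless motion analysis.

Single-view markerless pose estimation is good at image-plane coordinates and
poor at depth: the estimated depth of a joint carries a systematic,
height-correlated error (the reconstructed body appears tilted), plus noise
and occlusion dropouts. `dualskel` fuses a frontal landmark stream with a
nominally 90° side-view stream — the side camera sees the subject's depth
axis side-on, where it is reliable — to produce a corrected 3-D skeleton.
It is aimed at rehabilitation-exercise analysis (upper-limb movements of a
standing subject recorded at 30 Hz), where accurate wrist/elbow depth
trajectories matter and marker-based capture is impractical.

The package operates downstream of any pose-estimation backend: its input is
two per-frame 3-D landmark streams (frame, time, joint, x/y/z, visibility),
not video.

## Method

Given front and side streams S_f, S_s with positions p = (x, y, z) (y
vertical, z depth along the front camera's optical axis), a session is
processed in four stages:

1. **Spatial registration.** The side skeleton is mapped into the front frame
   by a rotation θ about the vertical axis and a translation **T**,
   estimated by minimizing the summed joint misalignment
   E_spatial = Σᵢ ‖J_f(i) − R_y(θ)·J_s(i) − **T**‖₂
   over a still calibration window (θ grid search with closed-form **T** per
   angle, then bounded scalar refinement).
2. **Temporal registration.** Integer frame offsets (Δt_f, Δt_s) are scored
   by the mean inter-stream depth disagreement
   E_sync = mean_t Σᵢ |z_f(i, t+Δt_f) − z_s(i, t+Δt_s)|
   against an adjustment cost C = |Δt_f| + |Δt_s|; the Pareto front over
   (E_sync, C) is computed and an operating point selected by a normalized
   trade-off weight (default: the accuracy end of the front).
3. **Depth-bias correction.** The signed residual e = z_front − z_side is
   regressed on joint height, e ≈ k_e·y + b_e, over the calibration window;
   front depths are corrected as z ← z − (k_e·y + b_e) wherever the side
   view cannot supply depth directly.
4. **Fusion with Kalman gap-filling.** Per frame and joint: x, y come from
   the front view and z from the registered side view; joints seen only
   frontally get the bias-corrected front depth; joints seen only from the
   side are inserted with the signed per-joint discrepancy adjustment
   z + α·E_d; joints seen by neither camera are bridged by an independent
   per-joint constant-velocity Kalman filter (6-D state, position +
   velocity, R calibrated from a static segment, Q = 10⁻⁶·I). Every fused
   joint carries a provenance tag (`front`, `side+aEd`, `kalman`).

Accuracy is reported as per-joint mean ± SD absolute depth error (population
SD) and MPJPE (mean per-joint position error, mm).

Because real paired recordings of this kind are rarely shareable, the
package includes a synthetic two-camera rig (`dualskel.simulate`) that
generates ground-truthed exercise sessions — analytic kinematic-chain
motion, height-correlated frontal depth bias, per-axis noise with an
optional dark-clothing contrast factor, side-view occlusion and an
inter-stream time offset — so every stage is testable against exact truth.

## Worked example

```python
from dualskel import (ExerciseSpec, default_rig, simulate_pair,
                      depth_error_series, DualViewFusion)

front, side, gt = simulate_pair(ExerciseSpec(kind="arm_flexion"),
                                default_rig(), seed=42)
res = DualViewFusion(front, side).fit()
print(res.summary())
```

```
              Dual-View Skeleton Fusion Results
==============================================================
Frames (front/side)               300/300
Frame rate                        30 Hz
Joints used for registration      13
--------------------------------------------------------------
Rig rotation theta (deg)           89.4189
Rig translation T (m)             ( 0.1514,  0.0105, -0.0742)
Spatial misalignment E (m)         66.381863
Registration converged            True
Temporal offsets (dt_f, dt_s)     (-5, 0)
Sync error E_sync (m)              1.338448
Pareto front size                 21
Depth-bias slope k_e               0.24898
Depth-bias intercept b_e (m)      -0.22278
Bias fit RMSE (m)                  0.013975  (n=643)
Residual discrepancy E_d (m)       0.142319
Measurement sigma (m)             (0.01021, 0.009802, 0.009761)
==============================================================
```

The rig that generated this session had θ = 90°, **T** = (0.15, 0.01, −0.08) m,
a 5-frame inter-stream offset, depth-bias line (0.25, −0.22) and 1 cm noise —
all recovered above (the offset appears as dt_f = −5 against the delayed side
stream, i.e. offset difference +5).

```python
out = res.evaluate(gt.world)           # against the simulator's ground truth
```

```
right_elbow: mean=0.0100 m sd=0.0072 m n=295
right_wrist: mean=0.0090 m sd=0.0064 m n=295
mpjpe: 16.41 mm
front-only mean depth error: 0.0760 m
```

Fusion reduces the mean wrist/elbow depth error from 0.076 m (front camera
alone) to below 0.01 m on this session.

The same pipeline is scriptable from the shell:

```bash
dualskel simulate --exercise arm_flexion --seed 42 --out data/
dualskel calibrate --front data/front.csv --side data/side.csv --out cal.yaml
dualskel fuse --front data/front.csv --side data/side.csv \
              --calibration cal.yaml --out fused.csv
dualskel evaluate --estimate fused.csv --truth data/truth.csv
```

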