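# Methods

## Problem setting and coordinate conventions

Markerless pose backends estimate per-frame 3-D joint positions from single
views. Image-plane coordinates are reliable; depth is not: frontal-view depth
errors are large, systematic and correlated with a joint's height (the
reconstructed body tilts — upper body toward the camera, lower body away).
`dualskel` corrects this by fusing a second, nominally orthogonal side view,
for which the subject's depth axis is an image-plane axis.

All coordinates are right-handed with x lateral, y vertical (up), z depth
along the front camera's optical axis, in meters. Streams are fixed-rate
(default 30 Hz); variable-rate input is rejected rather than resampled
because temporal registration operates in whole-frame offsets. A joint
observation is either present (position + visibility ≥ threshold, default
0.5) or absent; absent positions are NaN-backed and guarded — no operation
ever reads them.

## Spatial registration

The rig is modeled as a session-constant rotation θ about the vertical axis
plus a translation **T** (registration is rotate-then-translate:
`world = R_y(θ)·side + T`; the composition order is recorded in the
calibration file). The misalignment score is the window-summed Euclidean
distance over mutually visible joints. The estimator scans θ over
nominal ± 15° in 1° steps, solving **T** in closed form at each angle (mean
per-joint difference — the least-squares centroid shift), then refines θ by
bounded derivative-free scalar minimization (cap 200 iterations, tolerance
10⁻⁶). The 4-parameter problem is separable in **T**, so this is
deterministic and cheap; only Y-rotation is modeled (out-of-plane rotation
is a known limitation of the approach, see below).

Registration runs on a still calibration window (default frames 40–90,
mirroring the initial synchronization phase of a recorded session) so that a
not-yet-estimated temporal offset cannot corrupt it.

**Identifiability caveat.** A constant depth offset splits arbitrarily
between T_z and the depth-bias intercept b_e: adding c to one and
subtracting it from the other changes nothing observable between the two
streams. Registration therefore absorbs the window-mean front depth bias
into T_z, and the composite front-depth correction map (T_z + b_e) is the
identifiable quantity. For the sign-changing tilt bias the simulator
emulates by default this constant is near zero; for a one-sided bias the
fused depth inherits the window-mean as a uniform offset.

## Temporal registration

Both offsets (Δt_f, Δt_s) are searched on an integer grid (default ±60
frames). The synchronization error is the mean over overlapping frames of
the summed absolute depth disagreement across mutually present joints;
averaging (rather than summing) over the overlap keeps candidates with
different overlap lengths comparable. The adjustment cost defaults to
C = |Δt_f| + |Δt_s| (a unitless buffer/latency proxy; injectable). Only the
difference Δt_s − Δt_f moves the error; the 2-D grid is kept and the
degeneracy resolved by the cost term and a deterministic tie-break (smaller
|Δt_f|+|Δt_s|, then smaller Δt_f).

The non-dominated (Pareto) set over (E_sync, C) is extracted by an
O(n log n) plane sweep (verified in tests against an O(n²) all-pairs
oracle), and one member selected by minimizing
`tradeoff·ê + (1−tradeoff)·ĉ` on min-max-normalized objectives. The default
trade-off weight is 1.0 — the accuracy end of the front — because the cost
objective's role here is to break the offset-pair degeneracy, not to trade
away synchronization accuracy; deployments that must bound buffering can
lower it and pick a cheaper operating point from the same front.

## Depth-bias model

Two linear models are kept:

* the residual model (the main correction): signed inter-view residual
  e = z_front − z_side regressed on joint height over all mutually visible
  (joint, frame) pairs of the calibration window, e ≈ k_e·y + b_e; front
  depths are corrected by subtracting the predicted residual. OLS via
  least squares; degenerate windows (all samples at one height) are
  rejected.
* the height line y = k·z + b fitted within a single stream, whose inversion
  z = (y − b)/k supplies a height-implied depth. This is exposed as a
  fallback for frames where the side view is entirely absent
  (single-camera operation); its prose interpretation is ambiguous in the
  source method (it returns a depth, not an error), so both readings exist
  behind an explicit choice rather than one silently standing for the
  other.

The inter-view discrepancy is reported in two forms, deliberately distinct:
the absolute per-frame sum (diagnostic E_d total — an unsigned total cannot
restore direction) and the signed per-joint windowed mean that drives the
directional adjustment z + α·E_d of side-inserted joints. α defaults to 1.0
(full correction). When the residual regression is active the signed map is
computed on corrected front depths, so it captures only per-joint residual
mismatch and is near zero on well-calibrated sessions.

## Kalman tracking and gap-filling

One independent 6-state constant-velocity filter per joint: state
(x, y, z, ẋ, ẏ, ż), transition advancing positions by velocity·Δt
(Δt = 1/30 s), zero control input, observation matrix selecting the position
block (the backend measures positions, not velocities — a literal 6×6
identity observation would require velocity measurements that do not exist).
R = diag(σ_x², σ_y², σ_z²) comes from per-axis sample variances of a static
segment (protocol: a motionless subject for ~30 s; the pipeline reuses the
calibration window and falls back to σ = 1 cm per axis when no usable still
segment exists). Q = q·I with q = 10⁻⁶ for numerical conditioning.
Initialization: first present observation, zero velocity, P₀ = I. Gaps are
bridged by pure prediction; after `max_gap` (default 30) unobserved frames
the filter re-initializes at the next observation, because unobserved
constant-velocity extrapolation diverges.

**Where the filter's output is used.** The filter state is updated by every
fused observation, but the fused output keeps the raw combined coordinates
for observed joints and uses filter predictions only to bridge frames unseen
by both cameras. With the deliberately small q the filter is sluggish:
measured on the default scenario it lags fast arm motion by several
centimeters, which would more than undo the fusion gains if applied to
observed joints, while remaining exactly what is wanted for coasting through
short occlusions. Full-output smoothing stays available via
`FusionConfig.kalman_smooth_output` for slow-motion or high-noise settings.

## Fusion rule and ablations

Per frame and joint, in priority order: both views → x, y from front, z from
the registered side view; front only → bias-corrected front depth; side only
→ side position with the signed depth adjustment; neither → Kalman
prediction. Provenance (`front` / `side+aEd` / `kalman`) is recorded per
fused joint. The fused stream covers exactly the post-offset overlap and
inherits the front stream's frame indexing.

Three ablation switches lesion single stages, for controlled comparisons:
`kalman_on=False` fills both-view gaps with the last held value,
`regression_on=False` keeps raw front depths, `sync_on=False` pairs frames
by nearest timestamp (no offset compensation). On the default synthetic
scenario the full pipeline's median wrist/elbow depth error is ≤ every
single-lesion variant; the Kalman lesion ties it exactly when the front
camera never drops a joint (the gap-filling channel is then idle).

## Synthetic rig

The simulator emulates the recording setup the method targets: a standing
subject, 30 Hz, frontal camera plus nominally 90° side camera at
approximately equal height. World motion is an analytic kinematic chain
(pelvis→trunk→shoulder→elbow→wrist over a 13-joint catalog) driven by
raised-cosine shoulder-angle ramps — exercises: lateral arm raise
(abduction), forward raise (flexion), forward raise with horizontal sweep
(brachial adduction), both-arm flexion, and a static hold for noise
calibration. Trajectories are analytic rather than motion-capture replays so
ground truth is exact and parameter-free; segment lengths are constant to
machine precision. Every exercise starts and ends with a still hold
(default 3 s), providing the calibration window a real session's
synchronization phase would.

Observation models: the front view adds per-axis Gaussian noise (default
σ = 1 cm, multiplied by a contrast factor ≥ 1 to emulate dark-clothing
degradation — noise inflation, not position bias, matching the reduced
contrast/feature-detection explanation of that effect) and a
height-correlated depth bias z += k_e·y + b_e. The default bias
(k_e = 0.25, b_e = −0.22) is a sign-changing body tilt — upper body toward
the camera, lower body away, crossing zero near hip height, magnitudes
≈ 0.1–0.3 m at the extremities — the pattern single-view frontal
reconstructions actually show. The side view is expressed in the side
camera's local frame (inverse of the rig registration), has unbiased depth
and its own noise, drops contralateral or specified joints (per-joint
Bernoulli dropout plus deterministic always-hidden masks) and starts with a
configurable integer frame offset (out-of-range source frames clamp to the
stream ends, which coincide with the still holds). Everything is bit-exactly
reproducible from (spec, rig, seed).

What the simulator does **not** emulate: lens distortion and focal-length
scale errors, rolling shutter, soft-tissue/clothing articulation, backend-
specific landmark jitter spectra (noise is white), correlated multi-joint
occlusion events, and out-of-plane camera rotation. Passing tests therefore
demonstrate correctness of the registration/correction/fusion machinery
under the stated error model, not field accuracy of any particular pose
backend.

## Evaluation

Depth error is the per-frame absolute difference |z_est − z_ref| per joint,
summarized as mean and population (1/N) standard deviation (the sample form
is available behind a flag for cross-checks); whole-skeleton accuracy is
MPJPE in millimeters over mutually present joints. In synthetic studies the
reference is ground truth; with two streams only, the registered side depth
is the reference. Condition studies (single- vs dual-camera, unobstructed
vs partially obstructed, frontal vs non-frontal) run matched seeds per
condition and compare per-seed trial means with a paired two-sided t-test;
trials are the pairing unit, and degenerate inputs (all-zero or
zero-variance differences) take explicit reporting paths instead of
producing undefined statistics. Single-seed studies are reported but flagged
underpowered.

## Numerical choices and problem sizes

* Registration: grid step 1°, refinement tolerance 10⁻⁶, iteration cap 200;
  ≥ 3 mutually visible joint samples required.
* Temporal search: default half-window ±60 frames, minimum overlap 10
  frames; E_sync is evaluated once per offset difference and broadcast over
  the grid.
* Kalman: innovation covariance conditioning is checked (cond > 10¹⁵
  rejected); covariance symmetry/PSD is asserted to eigenvalue −10⁻⁹ in
  tests.
* CSV I/O uses round-trip float formatting, so write→read is exact and
  repeated writes are byte-identical.
* Test and acceptance problem sizes: 10 s sessions (300 frames, 13 joints);
  50 seeds for registration/bias/ablation studies, 20 for temporal
  recovery, 100 for the end-to-end benchmark — sizes at which every
  stochastic margin observed is wide relative to its threshold.

## Known limitations

* Only Y-axis rotation is modeled; a rig with out-of-plane tilt leaves
  systematic residuals the linear bias model partially absorbs.
* The T_z ↔ b_e split is unidentifiable (see above); absolute depth is
  anchored to the front camera's frame only up to the window-mean bias.
* The bias model is linear in height by design; nonlinear correctors are
  out of scope.
* Calibration is per-session; drift within a session is not re-estimated.
* Offsets are whole frames; sub-frame interpolation is not attempted.
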