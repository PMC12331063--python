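"""Synthetic two-camera rig: ground-truthed paired landmark streams.

Emulates a standing subject performing upper-limb rehabilitation exercises in
front of a 30 Hz frontal camera with a nominally 90° side camera, so that
every pipeline stage — spatial and temporal registration, depth-bias fitting,
Kalman gap-filling and end-to-end fusion — can be exercised against an exact,
fully present world trajectory.

World motion is an analytic kinematic chain (pelvis→trunk→shoulder→elbow→
wrist) driven by raised-cosine shoulder-angle ramps, so segment lengths are
constant by construction and the ground truth is parameter-free.  Every
exercise starts and ends with a still hold, mirroring the initial
synchronization phase of a real session and providing the static segment the
measurement-noise and depth-bias calibrations rely on.

The two views corrupt the truth differently:

* front — per-axis Gaussian noise (optionally inflated by a contrast factor
  emulating dark clothing) plus a height-correlated depth bias
  ``z += k_e·y + b_e``, the dominant error of single-view frontal depth;
* side — expressed in the side camera's local frame (the inverse of the rig's
  rotate-then-translate registration), unbiased depth, its own noise, optional
  contralateral-joint occlusion (the side camera cannot see the far arm) and
  an integer start-time offset.

Occlusion is per-joint Bernoulli dropout plus optional deterministic
always-hidden masks.  Everything is reproducible bit-exactly from
``(spec, rig, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .geometry import rotation_y_matrix
from .skeleton import BODY13, SkeletonSequence, StreamMetadata, write_landmark_stream

__all__ = [
    "ExerciseSpec",
    "RigSpec",
    "OcclusionSpec",
    "SubjectScale",
    "GroundTruth",
    "generate_motion",
    "observe_front",
    "observe_side",
    "make_paired_dataset",
    "default_rig",
]

EXERCISES = ("arm_abduction", "arm_flexion", "brachial_adduction", "both_arm_flexion", "static")


@dataclass(frozen=True)
class SubjectScale:
    """Segment lengths (m) of the standing subject."""

    hip_height: float = 0.95
    trunk: float = 0.50       # hip to shoulder line
    head: float = 0.25        # shoulder line to head reference
    shoulder_halfwidth: float = 0.20
    hip_halfwidth: float = 0.12
    upper_arm: float = 0.30
    forearm: float = 0.27
    thigh: float = 0.45
    shank: float = 0.45


@dataclass(frozen=True)
class ExerciseSpec:
    """One recorded exercise: kind, duration, rate and shoulder excursion."""

    kind: str = "arm_flexion"
    duration: float = 10.0
    frame_rate: float = 30.0
    amplitude: float = np.deg2rad(160.0)  # shoulder excursion, radians
    hold: float = 3.0                     # still segment at start and end, s
    subject: SubjectScale = field(default_factory=SubjectScale)

    def __post_init__(self) -> None:
        if self.kind not in EXERCISES:
            raise ConfigError(f"unknown exercise kind {self.kind!r}")
        if not self.duration > 0:
            raise ConfigError("duration must be > 0")
        if not 0 < self.amplitude <= np.pi:
            raise ConfigError("amplitude must be in (0, pi]")


@dataclass(frozen=True)
class OcclusionSpec:
    """Per-view dropout: Bernoulli probability per joint + deterministic masks."""

    dropout: dict[str, float] = field(default_factory=dict)   # joint -> p in [0,1]
    always_hidden: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for j, p in self.dropout.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"dropout probability for {j!r} must be in [0,1]")


@dataclass(frozen=True)
class RigSpec:
    """True rig parameters the pipeline must recover."""

    true_theta: float = 90.0
    true_T: tuple[float, float, float] = (0.15, 0.01, -0.08)
    time_offset: int = 0
    front_depth_bias: tuple[float, float] = (0.0, 0.0)  # (k_e, b_e)
    noise_sigma: tuple[float, float, float] = (0.0, 0.0, 0.0)
    contrast_factor: float = 1.0
    front_occlusion: OcclusionSpec = field(default_factory=OcclusionSpec)
    side_occlusion: OcclusionSpec = field(default_factory=OcclusionSpec)

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.noise_sigma):
            raise ConfigError("noise_sigma must be >= 0")
        if self.contrast_factor < 1:
            raise ConfigError("contrast_factor must be >= 1")


def default_rig(
    bias: tuple[float, float] = (0.25, -0.22),
    sigma: float = 0.01,
    side_dropout: float = 0.10,
    time_offset: int = 5,
) -> RigSpec:
    """The default study scenario.

    The frontal depth bias is a sign-changing body tilt — upper body leaning
    toward the camera, lower body away, crossing zero near hip height — with
    magnitudes of roughly 0.1–0.3 m at the extremities (≈0.3 m at a raised
    wrist); observation noise is 1 cm per axis, the side view drops the
    moving-arm joints 10 % of frames, and the streams are offset by 5 frames.
    """
    return RigSpec(
        true_theta=90.0,
        true_T=(0.15, 0.01, -0.08),
        time_offset=time_offset,
        front_depth_bias=bias,
        noise_sigma=(sigma, sigma, sigma),
        side_occlusion=OcclusionSpec(
            dropout={"right_elbow": side_dropout, "right_wrist": side_dropout}
        ),
    )


@dataclass(frozen=True)
class GroundTruth:
    """Exact world trajectory plus the rig/exercise that generated it."""

    world: SkeletonSequence
    rig: RigSpec
    exercise: ExerciseSpec
    seed: int


def _raised_cosine_profile(t: np.ndarray, hold: float, duration: float) -> np.ndarray:
    """0→1→0 smooth activation: still, raised-cosine up, raised-cosine down."""
    move = max(duration - 2 * hold, 1e-9)
    half = move / 2.0
    s = np.zeros_like(t)
    rising = (t >= hold) & (t < hold + half)
    falling = (t >= hold + half) & (t < hold + move)
    s[rising] = 0.5 * (1 - np.cos(np.pi * (t[rising] - hold) / half))
    s[falling] = 0.5 * (1 + np.cos(np.pi * (t[falling] - hold - half) / half))
    return s


def generate_motion(spec: ExerciseSpec, seed: int = 0) -> GroundTruth:
    """Exact world trajectory of the requested exercise.

    The subject stands at the origin facing the front camera (+z toward the
    camera).  The moving arm stays extended (elbow locked), so elbow and
    wrist trace circles of constant radius about the shoulder — segment
    lengths are constant to machine precision.
    """
    sub = spec.subject
    n = int(round(spec.duration * spec.frame_rate))
    t = np.arange(n) / spec.frame_rate
    phi = spec.amplitude * _raised_cosine_profile(t, spec.hold, spec.duration)
    if spec.kind == "static":
        phi = np.zeros_like(phi)

    y_hip = sub.hip_height
    y_sh = y_hip + sub.trunk
    base = {
        "head": (0.0, y_sh + sub.head, 0.0),
        "right_shoulder": (sub.shoulder_halfwidth, y_sh, 0.0),
        "left_shoulder": (-sub.shoulder_halfwidth, y_sh, 0.0),
        "right_hip": (sub.hip_halfwidth, y_hip, 0.0),
        "left_hip": (-sub.hip_halfwidth, y_hip, 0.0),
        "right_knee": (sub.hip_halfwidth, y_hip - sub.thigh, 0.0),
        "left_knee": (-sub.hip_halfwidth, y_hip - sub.thigh, 0.0),
        "right_ankle": (sub.hip_halfwidth, y_hip - sub.thigh - sub.shank, 0.0),
        "left_ankle": (-sub.hip_halfwidth, y_hip - sub.thigh - sub.shank, 0.0),
    }
    pos = np.zeros((n, len(BODY13), 3))
    for j, name in enumerate(BODY13):
        if name in base:
            pos[:, j, :] = np.asarray(base[name])

    def arm(side_sign: float, angle: np.ndarray, plane: str):
        """Unit direction of an extended arm at elevation *angle* from 'down'."""
        down = np.stack([np.zeros_like(angle), -np.cos(angle), np.zeros_like(angle)], axis=1)
        if plane == "frontal":      # abduction: lifts laterally (x–y plane)
            down[:, 0] = side_sign * np.sin(angle)
        elif plane == "sagittal":   # flexion: lifts forward (y–z plane)
            down[:, 2] = np.sin(angle)
        else:  # pragma: no cover
            raise ConfigError(plane)
        return down

    def place_arm(prefix: str, side_sign: float, direction: np.ndarray):
        sh = pos[:, BODY13.index(f"{prefix}_shoulder"), :]
        pos[:, BODY13.index(f"{prefix}_elbow"), :] = sh + sub.upper_arm * direction
        pos[:, BODY13.index(f"{prefix}_wrist"), :] = sh + (sub.upper_arm + sub.forearm) * direction

    zeros = np.zeros_like(phi)
    rest_r = arm(+1.0, zeros, "frontal")
    rest_l = arm(-1.0, zeros, "frontal")
    if spec.kind == "arm_abduction":
        place_arm("right", +1.0, arm(+1.0, phi, "frontal"))
        place_arm("left", -1.0, rest_l)
    elif spec.kind == "arm_flexion":
        place_arm("right", +1.0, arm(+1.0, phi, "sagittal"))
        place_arm("left", -1.0, rest_l)
    elif spec.kind == "both_arm_flexion":
        place_arm("right", +1.0, arm(+1.0, phi, "sagittal"))
        place_arm("left", -1.0, arm(-1.0, phi, "sagittal"))
    elif spec.kind == "brachial_adduction":
        # raise forward to shoulder level, then adduct horizontally toward the
        # face midline with the elbow extended; both phases share the profile
        lift = np.minimum(phi, np.pi / 2)
        sweep = np.maximum(phi - np.pi / 2, 0.0)
        direction = np.stack(
            [
                -np.sin(lift) * np.sin(sweep),
                -np.cos(lift),
                np.sin(lift) * np.cos(sweep),
            ],
            axis=1,
        )
        place_arm("right", +1.0, direction)
        place_arm("left", -1.0, rest_l)
    else:  # static
        place_arm("right", +1.0, rest_r)
        place_arm("left", -1.0, rest_l)

    world = SkeletonSequence(
        view="truth",
        frame_rate=spec.frame_rate,
        catalog=BODY13,
        positions=pos,
        present=np.ones((n, len(BODY13)), dtype=bool),
        metadata=StreamMetadata(source=f"synthetic:{spec.kind}"),
    )
    return GroundTruth(world=world, rig=RigSpec(), exercise=spec, seed=seed)


def _apply_occlusion(present: np.ndarray, catalog, occ: OcclusionSpec, rng) -> np.ndarray:
    present = present.copy()
    for joint, p in occ.dropout.items():
        j = catalog.index(joint)
        present[:, j] &= rng.random(present.shape[0]) >= p
    for joint in occ.always_hidden:
        present[:, catalog.index(joint)] = False
    return present


def observe_front(gt: GroundTruth, rig: RigSpec | None = None, seed: int | None = None) -> SkeletonSequence:
    """Frontal-camera stream: noisy world coordinates with biased depth."""
    rig = rig or gt.rig
    seed = gt.seed if seed is None else seed
    rng = np.random.default_rng((int(seed), 0xF0))
    w = gt.world
    pos = w.positions.copy()
    k_e, b_e = rig.front_depth_bias
    pos[:, :, 2] += k_e * w.positions[:, :, 1] + b_e
    sigma = np.asarray(rig.noise_sigma) * rig.contrast_factor
    pos += rng.normal(0.0, 1.0, pos.shape) * sigma
    present = _apply_occlusion(w.present, list(w.catalog), rig.front_occlusion, rng)
    return SkeletonSequence(
        "front", w.frame_rate, w.catalog, pos, present,
        metadata=StreamMetadata(source="synthetic:front"),
    )


def observe_side(gt: GroundTruth, rig: RigSpec | None = None, seed: int | None = None) -> SkeletonSequence:
    """Side-camera stream in its local frame, delayed by the rig time offset.

    The local frame is the inverse of the registration map: with the rig's
    rotate-then-translate convention ``world = R_y(θ)·local + T``, the camera
    records ``local = R_y(−θ)·(world − T)``.  Side depth is unbiased — the
    side camera views the subject's depth axis side-on.  ``time_offset = k``
    means side frame i shows world frame i − k (clamped at the stream ends,
    which coincide with the still holds).
    """
    rig = rig or gt.rig
    seed = gt.seed if seed is None else seed
    rng = np.random.default_rng((int(seed), 0x51))
    w = gt.world
    n = w.frame_count
    src = np.clip(np.arange(n) - rig.time_offset, 0, n - 1)
    Rinv = rotation_y_matrix(-rig.true_theta)
    T = np.asarray(rig.true_T)
    pos = (w.positions[src] - T) @ Rinv.T
    pos += rng.normal(0.0, 1.0, pos.shape) * np.asarray(rig.noise_sigma)
    present = _apply_occlusion(w.present[src], list(w.catalog), rig.side_occlusion, rng)
    return SkeletonSequence(
        "side", w.frame_rate, w.catalog, pos, present,
        metadata=StreamMetadata(source="synthetic:side"),
    )


def simulate_pair(
    exercise: ExerciseSpec,
    rig: RigSpec,
    seed: int = 0,
) -> tuple[SkeletonSequence, SkeletonSequence, GroundTruth]:
    """Convenience: world truth plus both observed streams for one session."""
    gt = generate_motion(exercise, seed)
    gt = GroundTruth(world=gt.world, rig=rig, exercise=exercise, seed=seed)
    return observe_front(gt), observe_side(gt), gt


def make_paired_dataset(
    exercise: ExerciseSpec,
    rig: RigSpec,
    seed: int,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write front/side/truth CSVs plus a YAML manifest of true parameters."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    front, side, gt = simulate_pair(exercise, rig, seed)
    paths = {
        "front": out_dir / "front.csv",
        "side": out_dir / "side.csv",
        "truth": out_dir / "truth.csv",
        "manifest": out_dir / "manifest.yaml",
    }
    write_landmark_stream(front, paths["front"])
    write_landmark_stream(side, paths["side"])
    write_landmark_stream(gt.world, paths["truth"])
    def _plain(obj):
        """Recursively coerce numpy scalars/containers to YAML-safe types."""
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.integer):
            return int(obj)
        return obj

    manifest = {
        "seed": int(seed),
        "exercise": _plain(asdict(exercise)),
        "rig": _plain({
            "true_theta": rig.true_theta,
            "true_T": list(rig.true_T),
            "time_offset": rig.time_offset,
            "front_depth_bias": list(rig.front_depth_bias),
            "noise_sigma": list(rig.noise_sigma),
            "contrast_factor": rig.contrast_factor,
            "front_occlusion": {
                "dropout": dict(rig.front_occlusion.dropout),
                "always_hidden": list(rig.front_occlusion.always_hidden),
            },
            "side_occlusion": {
                "dropout": dict(rig.side_occlusion.dropout),
                "always_hidden": list(rig.side_occlusion.always_hidden),
            },
        }),
        "files": {k: v.name for k, v in paths.items() if k != "manifest"},
    }
    paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8")
    return paths
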