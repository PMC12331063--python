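"""Per-joint constant-velocity Kalman filtering and gap-filling.

Each joint is tracked by an independent 6-state linear-Gaussian filter,
state ``x = (x, y, z, ẋ, ẏ, ż)``, under a first-order constant-velocity
motion model: positions advance by velocity·Δt each frame (Δt = 1/30 s by
default, matching the 30 Hz streams), zero control input.  The observation
matrix selects the position block — the measurement is the 3-D landmark
itself, with no velocity channel.

Measurement noise R = diag(σ_x², σ_y², σ_z²) is calibrated from a static
recording (per-axis sample variances of a motionless subject); a small
process-noise term q·I (default q = 1e-6) keeps the covariance recursion
well conditioned.  The filter is initialized at the first present observation
with zero velocity and P₀ = I.

During occlusions the filter coasts on pure prediction; gaps longer than
``max_gap`` frames trigger re-initialization at the next observation, because
an unobserved constant-velocity extrapolation diverges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, ConfigError, EmptyResultError
from .skeleton import SkeletonSequence

__all__ = [
    "FilterState",
    "NoiseModel",
    "KalmanConfig",
    "transition_matrix",
    "OBSERVATION_MATRIX",
    "predict_step",
    "update_step",
    "calibrate_measurement_noise",
    "JointTracker",
    "track_joint",
    "fill_missing",
]

# H selects the position block: the backend measures joint positions, not
# velocities, so the "identity" observation acts on positions only.
OBSERVATION_MATRIX = np.hstack([np.eye(3), np.zeros((3, 3))])


@dataclass
class FilterState:
    """6-D state (position + velocity) with covariance."""

    x: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).reshape(6)
        self.P = np.asarray(self.P, dtype=float).reshape(6, 6)

    @property
    def position(self) -> np.ndarray:
        return self.x[:3]

    @property
    def velocity(self) -> np.ndarray:
        return self.x[3:]

    def check(self, tol: float = 1e-9) -> None:
        """Assert P symmetric positive semidefinite (to eigenvalue −tol)."""
        if not np.allclose(self.P, self.P.T, atol=1e-9):
            raise ConfigError("covariance P is not symmetric")
        w = np.linalg.eigvalsh(0.5 * (self.P + self.P.T))
        if w.min() < -tol:
            raise ConfigError(f"covariance P not PSD (min eigenvalue {w.min():.3e})")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement variances per axis (m²) and process-noise scale."""

    sigma2: tuple[float, float, float] = (1e-4, 1e-4, 1e-4)  # (1 cm)² default
    q: float = 1e-6

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sigma2):
            raise ConfigError("measurement variances must be >= 0")
        if not self.q > 0:
            raise ConfigError("process-noise scale q must be > 0")

    @property
    def R(self) -> np.ndarray:
        return np.diag(self.sigma2)


@dataclass(frozen=True)
class KalmanConfig:
    dt: float = 1.0 / 30.0
    max_gap: int = 30  # frames of pure prediction before re-initialization

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ConfigError("dt must be > 0")


def transition_matrix(dt: float) -> np.ndarray:
    """Constant-velocity transition: positions advance by velocity·dt."""
    A = np.eye(6)
    A[0, 3] = A[1, 4] = A[2, 5] = dt
    return A


def initial_state(position) -> FilterState:
    """First present observation, zero velocity, P₀ = I."""
    x0 = np.concatenate([np.asarray(position, dtype=float), np.zeros(3)])
    return FilterState(x=x0, P=np.eye(6))


def predict_step(state: FilterState, cfg: KalmanConfig, noise: NoiseModel) -> FilterState:
    """Time update: x ← A x,  P ← A P Aᵀ + q·I."""
    A = transition_matrix(cfg.dt)
    x = A @ state.x
    P = A @ state.P @ A.T + noise.q * np.eye(6)
    return FilterState(x=x, P=P)


def update_step(state: FilterState, z_meas, noise: NoiseModel) -> FilterState:
    """Measurement update with gain K = P Hᵀ (H P Hᵀ + R)⁻¹.

    The covariance update uses the (I − K H) P form.
    """
    H = OBSERVATION_MATRIX
    z = np.asarray(z_meas, dtype=float).reshape(3)
    S = H @ state.P @ H.T + noise.R
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e15:
        raise ConfigError(f"innovation covariance numerically singular (cond {cond:.2e})")
    K = state.P @ H.T @ np.linalg.inv(S)
    x = state.x + K @ (z - H @ state.x)
    P = (np.eye(6) - K @ H) @ state.P
    return FilterState(x=x, P=P)


def calibrate_measurement_noise(
    static_seq: SkeletonSequence,
    joint: str,
    min_frames: int = 30,
    q: float = 1e-6,
) -> NoiseModel:
    """Per-axis sample variances of a joint observed on a motionless subject.

    The calibration protocol records a static subject (~30 s) so every
    deviation from the mean is measurement noise.
    """
    j = static_seq.joint_index(joint)
    mask = static_seq.present[:, j]
    if mask.sum() < min_frames:
        raise CalibrationError(
            f"joint {joint!r} present in only {int(mask.sum())} frames (< {min_frames})"
        )
    obs = static_seq.positions[mask, j, :]
    var = obs.var(axis=0, ddof=1)
    return NoiseModel(sigma2=tuple(float(v) for v in var), q=q)


class JointTracker:
    """Streaming per-joint filter with gap handling.

    ``step(observation)`` advances one frame and returns the filtered
    position; *observation* is a 3-vector or None (occluded).  Before the
    first observation arrives the tracker has no state and returns None.
    """

    def __init__(self, cfg: KalmanConfig | None = None, noise: NoiseModel | None = None):
        self.cfg = cfg or KalmanConfig()
        self.noise = noise or NoiseModel()
        self.state: FilterState | None = None
        self.gap = 0

    @property
    def initialized(self) -> bool:
        return self.state is not None

    def predict(self) -> FilterState | None:
        """Predicted (prior) state for the next frame without consuming it."""
        if self.state is None:
            return None
        return predict_step(self.state, self.cfg, self.noise)

    def step(self, observation) -> np.ndarray | None:
        if observation is None:
            if self.state is None:
                return None
            self.gap += 1
            if self.gap > self.cfg.max_gap:
                # extrapolation diverged past usefulness; wait for data
                self.state = None
                return None
            self.state = predict_step(self.state, self.cfg, self.noise)
            return self.state.position.copy()
        obs = np.asarray(observation, dtype=float)
        if self.state is None:
            self.state = initial_state(obs)
            self.gap = 0
            return self.state.position.copy()
        self.gap = 0
        self.state = update_step(predict_step(self.state, self.cfg, self.noise), obs, self.noise)
        return self.state.position.copy()


@dataclass(frozen=True)
class TrackedPoint:
    position: np.ndarray | None
    P: np.ndarray | None
    was_observed: bool


def track_joint(
    observations,
    cfg: KalmanConfig | None = None,
    noise: NoiseModel | None = None,
) -> list[TrackedPoint]:
    """Filter a series of optional 3-vectors; output length equals input.

    Present observations run predict+update; absences coast on prediction
    (``was_observed=False``).  The first observation must be present.
    """
    observations = list(observations)
    if not observations or observations[0] is None:
        raise EmptyResultError("first observation absent: cannot initialize filter")
    if all(o is None for o in observations):
        raise EmptyResultError("all observations absent")
    tracker = JointTracker(cfg, noise)
    out: list[TrackedPoint] = []
    for obs in observations:
        pos = tracker.step(None if obs is None else obs)
        st = tracker.state
        out.append(
            TrackedPoint(
                position=None if pos is None else pos,
                P=None if st is None else st.P.copy(),
                was_observed=obs is not None,
            )
        )
    return out


def fill_missing(
    front_joint,
    side_joint_aligned,
    tracker: JointTracker,
    e_d_joint: float = 0.0,
    alpha: float = 1.0,
) -> tuple[np.ndarray | None, str]:
    """Resolve one joint for one fused frame and advance its tracker.

    Priority: front observation → side observation with the signed depth
    adjustment ``z + α·e_d`` → Kalman prediction.  The chosen value is passed
    through the tracker's predict/update cycle; the returned position is the
    tracker's filtered estimate (the raw choice when the tracker has no state
    yet).

    Returns ``(position | None, provenance tag)`` with tag in
    {"front", "side+aEd", "kalman"}.
    """
    if front_joint is not None:
        chosen = np.asarray(front_joint, dtype=float)
        tag = "front"
    elif side_joint_aligned is not None:
        chosen = np.asarray(side_joint_aligned, dtype=float).copy()
        chosen[2] = chosen[2] + alpha * e_d_joint
        tag = "side+aEd"
    else:
        pos = tracker.step(None)
        return (None if pos is None else pos), "kalman"
    filtered = tracker.step(chosen)
    return (chosen if filtered is None else filtered), tag
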