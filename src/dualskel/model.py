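"""Model/Results interface over the fusion pipeline.

:class:`DualViewFusion` is constructed from the two landmark streams plus a
config; ``fit()`` estimates the session calibration — rig rotation θ and
translation T, the temporal offset pair, the height→depth-residual line
(k_e, b_e) and the measurement-noise model — and returns a
:class:`DualViewFusionResults` carrying the estimates, their fit diagnostics,
a ``summary()`` table, and the ``fuse()`` / ``evaluate()`` / ``plot_depth()``
methods that consume them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .evaluate import depth_error_series, mpjpe, summarize_error
from .fusion import FusedSkeleton, FusionConfig, SessionCalibration, calibrate_session, fuse_streams
from .skeleton import SkeletonSequence, StreamMetadata, read_landmark_stream

__all__ = ["DualViewFusion", "DualViewFusionResults"]


class DualViewFusion:
    """Dual-camera skeleton fusion model.

    Parameters
    ----------
    front, side
        The frontal and side landmark streams (same catalog and frame rate).
    config
        Pipeline configuration; defaults to :class:`FusionConfig`.

    Examples
    --------
    >>> model = DualViewFusion(front, side)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> fused = res.fuse()
    """

    def __init__(
        self,
        front: SkeletonSequence,
        side: SkeletonSequence,
        config: FusionConfig | None = None,
    ) -> None:
        if front.frame_rate != side.frame_rate:
            raise ConfigError("front and side streams must share one frame rate")
        self.front = front
        self.side = side
        self.config = config or FusionConfig()

    @classmethod
    def from_files(
        cls,
        front_path: str | Path,
        side_path: str | Path,
        config: FusionConfig | None = None,
        frame_rate: float = 30.0,
        units_scale: float = 1.0,
    ) -> "DualViewFusion":
        """Build the model from two landmark CSV files."""
        config = config or FusionConfig()
        meta = StreamMetadata(units_scale=units_scale)
        front = read_landmark_stream(
            front_path, meta, view="front", frame_rate=frame_rate,
            visibility_threshold=config.visibility_threshold,
        )
        side = read_landmark_stream(
            side_path, StreamMetadata(units_scale=units_scale), view="side",
            frame_rate=frame_rate, visibility_threshold=config.visibility_threshold,
            catalog=front.catalog,
        )
        return cls(front, side, config)

    def fit(self) -> "DualViewFusionResults":
        """Estimate the session calibration and wrap it in a results object."""
        calibration = calibrate_session(self.front, self.side, self.config)
        return DualViewFusionResults(self, calibration)


@dataclass
class DualViewFusionResults:
    """Fitted session calibration with diagnostics and downstream actions."""

    model: DualViewFusion
    calibration: SessionCalibration

    # ------------------------------------------------------------- estimates
    @property
    def theta(self) -> float:
        """Estimated rig rotation about the vertical axis (degrees)."""
        return self.calibration.alignment.params.theta

    @property
    def translation(self) -> np.ndarray:
        """Estimated rig translation T (m)."""
        return np.asarray(self.calibration.alignment.params.T)

    @property
    def offsets(self) -> tuple[int, int]:
        """Selected (Δt_f, Δt_s) frame offsets; (0, 0) when sync is disabled."""
        if self.calibration.pareto is None:
            return (0, 0)
        o = self.calibration.pareto.selected.offsets
        return (o.dt_f, o.dt_s)

    @property
    def depth_bias(self) -> tuple[float, float]:
        """Height→depth-residual line (k_e, b_e)."""
        return (self.calibration.bias.k_e, self.calibration.bias.b_e)

    @property
    def measurement_sigma(self) -> np.ndarray:
        """Calibrated per-axis measurement noise SD (m)."""
        return np.sqrt(np.asarray(self.calibration.noise.sigma2))

    # --------------------------------------------------------------- actions
    def fuse(self) -> FusedSkeleton:
        """Fuse the model's two streams under this calibration."""
        return fuse_streams(self.model.front, self.model.side, self.model.config, self.calibration)

    def evaluate(self, truth: SkeletonSequence, joints=("right_elbow", "right_wrist")) -> dict:
        """Depth-error summaries of the fused stream against a reference."""
        fused = self.fuse().sequence
        out = {
            joint: summarize_error(depth_error_series(fused, truth, joint))
            for joint in joints
        }
        out["mpjpe_mm"] = mpjpe(fused, truth)
        return out

    def save_calibration(self, path: str | Path) -> None:
        self.calibration.save(path)

    def plot_depth(self, joint: str, truth: SkeletonSequence | None = None, ax=None):
        """Depth trajectories (front raw vs fused, optionally truth) for a joint."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3.5))
        fused = self.fuse().sequence
        j = self.model.front.joint_index(joint)
        ax.plot(self.model.front.timestamps, self.model.front.positions[:, j, 2],
                label="front (raw)", alpha=0.6)
        jf = fused.joint_index(joint)
        ax.plot(fused.timestamps, fused.positions[:, jf, 2], label="fused")
        if truth is not None:
            jt = truth.joint_index(joint)
            ax.plot(truth.timestamps, truth.positions[:, jt, 2], "--", label="truth")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("depth z (m)")
        ax.set_title(f"{joint} depth")
        ax.legend()
        return ax

    # --------------------------------------------------------------- summary
    def summary(self) -> str:
        """Human-readable calibration summary table."""
        a = self.calibration.alignment
        b = self.calibration.bias
        lines = []
        w = 62
        lines.append("Dual-View Skeleton Fusion Results".center(w))
        lines.append("=" * w)
        lines.append(f"{'Frames (front/side)':<34}{self.model.front.frame_count}/"
                     f"{self.model.side.frame_count}")
        lines.append(f"{'Frame rate':<34}{self.model.front.frame_rate:g} Hz")
        lines.append(f"{'Joints used for registration':<34}{a.n_joints_used}")
        lines.append("-" * w)
        lines.append(f"{'Rig rotation theta (deg)':<34}{self.theta: .4f}")
        T = self.translation
        lines.append(f"{'Rig translation T (m)':<34}({T[0]: .4f}, {T[1]: .4f}, {T[2]: .4f})")
        lines.append(f"{'Spatial misalignment E (m)':<34}{a.e_spatial: .6f}")
        lines.append(f"{'Registration converged':<34}{a.converged}")
        if self.calibration.pareto is not None:
            sel = self.calibration.pareto.selected
            lines.append(f"{'Temporal offsets (dt_f, dt_s)':<34}{self.offsets}")
            lines.append(f"{'Sync error E_sync (m)':<34}{sel.e_sync: .6f}")
            lines.append(f"{'Pareto front size':<34}{len(self.calibration.pareto.front_set)}")
        else:
            lines.append(f"{'Temporal sync':<34}disabled")
        lines.append(f"{'Depth-bias slope k_e':<34}{b.k_e: .5f}")
        lines.append(f"{'Depth-bias intercept b_e (m)':<34}{b.b_e: .5f}")
        lines.append(f"{'Bias fit RMSE (m)':<34}{b.rmse: .6f}  (n={b.n_samples})")
        lines.append(f"{'Residual discrepancy E_d (m)':<34}"
                     f"{self.calibration.discrepancy.e_d_total: .6f}")
        s = self.measurement_sigma
        lines.append(f"{'Measurement sigma (m)':<34}({s[0]:.4g}, {s[1]:.4g}, {s[2]:.4g})")
        lines.append("=" * w)
        return "\n".join(lines)
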