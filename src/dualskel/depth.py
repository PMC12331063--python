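"""Height-correlated depth-error modelling and correction.

Single-view depth predictions carry a systematic error that correlates with a
joint's vertical position: in a frontal recording the upper body leans toward
the camera and the lower body away.  Two linear models capture this:

* :class:`HeightDepthRegression` — the raw height-on-depth line ``y = k·z + b``
  fitted within a stream; its inversion ``z = (y − b)/k`` supplies a
  height-implied depth used as the *single-view fallback* when no side view is
  available at all.
* :class:`DepthBiasModel` — the main correction: the signed inter-view depth
  residual ``e = z_front − z_side`` regressed on joint height over a
  calibration window, ``e ≈ k_e·y + b_e``.  Subtracting the predicted residual
  from a front depth reconciles it with the (reliable) side-view depth.

The inter-view discrepancy is kept in two forms: the absolute per-frame sum
(a diagnostic of overall disagreement) and a signed per-joint windowed mean
that drives the directional adjustment of inserted joints
(``z_adjusted = z + α·e_d``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, EmptyResultError
from .skeleton import SkeletonSequence

__all__ = [
    "HeightDepthRegression",
    "DepthBiasModel",
    "DepthDiscrepancy",
    "fit_height_depth_regression",
    "regression_implied_depth",
    "fit_depth_bias",
    "correct_depth",
    "depth_discrepancy",
    "adjust_depth",
]


@dataclass(frozen=True)
class HeightDepthRegression:
    """OLS line y = k·z + b relating joint height to predicted depth."""

    k: float
    b: float
    n_samples: int
    rmse: float


@dataclass(frozen=True)
class DepthBiasModel:
    """Signed front-minus-side depth residual as a linear function of height."""

    k_e: float
    b_e: float
    calibration_window: tuple[int, int] | None = None
    n_samples: int = 0
    rmse: float = 0.0

    def predict(self, y) -> np.ndarray:
        return self.k_e * np.asarray(y, dtype=float) + self.b_e


@dataclass(frozen=True)
class DepthDiscrepancy:
    """Windowed inter-view depth disagreement.

    ``e_d_total`` is the window-mean of the per-frame absolute sum over
    mutually visible joints; ``per_joint_signed`` the windowed mean of
    ``z_front − z_side`` per joint (NaN-free: joints never mutually visible
    are omitted).
    """

    per_joint_signed: dict[str, float]
    e_d_total: float


def _ols_line(x: np.ndarray, yv: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope/intercept/rmse of yv on x."""
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
    resid = yv - A @ coef
    rmse = float(np.sqrt(np.mean(resid**2)))
    return float(coef[0]), float(coef[1]), rmse


def fit_height_depth_regression(samples) -> HeightDepthRegression:
    """Fit y = k·z + b by ordinary least squares.

    *samples* is a sequence of ``(z, y)`` pairs in meters.
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DegenerateFitError("need >= 2 (z, y) samples")
    z, y = arr[:, 0], arr[:, 1]
    if np.ptp(z) == 0:
        raise DegenerateFitError("constant depth regressor; line is undefined")
    k, b, rmse = _ols_line(z, y)
    return HeightDepthRegression(k=k, b=b, n_samples=len(arr), rmse=rmse)


def regression_implied_depth(model: HeightDepthRegression, y: float) -> float:
    """Invert the height line: z = (y − b)/k."""
    if model.k == 0:
        raise DegenerateFitError("k = 0: height line is not invertible for depth")
    return (y - model.b) / model.k


def _window_slices(front: SkeletonSequence, side: SkeletonSequence, window):
    if window is None:
        lo = max(front.start_index, side.start_index)
        hi = min(front.start_index + front.frame_count, side.start_index + side.frame_count)
        window = (lo, hi)
    lo, hi = window
    fs = slice(lo - front.start_index, hi - front.start_index)
    ss = slice(lo - side.start_index, hi - side.start_index)
    if fs.start < 0 or ss.start < 0 or fs.stop > front.frame_count or ss.stop > side.frame_count:
        raise EmptyResultError(f"window {window} exceeds stream extents")
    return fs, ss, window


def fit_depth_bias(
    front: SkeletonSequence,
    side_aligned: SkeletonSequence,
    window: tuple[int, int] | None = None,
) -> DepthBiasModel:
    """Regress the signed residual z_front − z_side on joint height.

    Pools every mutually visible (joint, frame) pair in the calibration
    window; heights are the front-view y coordinates.
    """
    fs, ss, window = _window_slices(front, side_aligned, window)
    both = front.present[fs] & side_aligned.present[ss]
    if both.sum() < 2:
        raise DegenerateFitError("fewer than 2 mutually visible samples in window")
    y = front.positions[fs][both][:, 1]
    e = front.positions[fs][both][:, 2] - side_aligned.positions[ss][both][:, 2]
    if np.ptp(y) == 0:
        raise DegenerateFitError("degenerate heights: all samples at one height")
    k_e, b_e, rmse = _ols_line(y, e)
    return DepthBiasModel(k_e=k_e, b_e=b_e, calibration_window=window,
                          n_samples=int(both.sum()), rmse=rmse)


def correct_depth(z, y, model: DepthBiasModel):
    """Remove the height-predicted residual: z − (k_e·y + b_e)."""
    return z - model.predict(y)


def depth_discrepancy(
    front: SkeletonSequence,
    side_aligned: SkeletonSequence,
    window: tuple[int, int] | None = None,
) -> DepthDiscrepancy:
    """Windowed inter-view depth disagreement (absolute total + signed map)."""
    fs, ss, window = _window_slices(front, side_aligned, window)
    both = front.present[fs] & side_aligned.present[ss]
    if not both.any():
        raise EmptyResultError("no mutually visible joints in window")
    diff = front.positions[fs][:, :, 2] - side_aligned.positions[ss][:, :, 2]
    abs_sum_per_frame = np.where(both, np.abs(diff), 0.0).sum(axis=1)
    e_d_total = float(abs_sum_per_frame.mean())
    per_joint: dict[str, float] = {}
    for j, name in enumerate(front.catalog):
        m = both[:, j]
        if m.any():
            per_joint[name] = float(diff[m, j].mean())
    return DepthDiscrepancy(per_joint_signed=per_joint, e_d_total=e_d_total)


def adjust_depth(z: float, alpha: float, e_d_joint: float) -> float:
    """Directional depth adjustment of an inserted joint: z + α·e_d."""
    return z + alpha * e_d_joint
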