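"""Spatial registration of the side-view skeleton onto the front-view frame.

The two cameras form a nominally 90° rig, so registration is restricted to a
single rotation angle θ about the vertical (y) axis plus a 3-D translation T —
a rig property estimated once per session, not per frame.  The misalignment
score is the sum over mutually visible joints of Euclidean inter-skeleton
distances; the optimizer exploits that for fixed θ the optimal T is available
in closed form (the mean per-joint difference), reducing the search to one
dimension over θ.

Composition order is fixed project-wide as rotate-then-translate:
``registered = R_y(θ) · side + T``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DegenerateGeometryError
from .skeleton import SkeletonFrame, SkeletonSequence

__all__ = [
    "AlignmentParams",
    "AlignmentResult",
    "rotation_y_matrix",
    "rotate_y",
    "translate",
    "spatial_error",
    "optimize_alignment",
]


def _normalize_angle(theta: float) -> float:
    """Map an angle in degrees to (−180, 180]."""
    t = (theta + 180.0) % 360.0 - 180.0
    return 180.0 if t == -180.0 else t


@dataclass(frozen=True)
class AlignmentParams:
    """Rigid registration parameters: translation T (m), y-rotation θ (deg)."""

    T: tuple[float, float, float]
    theta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", _normalize_angle(float(self.theta)))
        object.__setattr__(self, "T", tuple(float(v) for v in self.T))


@dataclass(frozen=True)
class AlignmentResult:
    """Fitted registration with its misalignment score.

    ``e_spatial`` is the window-summed joint distance (meters) at the optimum;
    results with fewer than 3 joints used are not trusted upstream.
    """

    params: AlignmentParams
    e_spatial: float
    n_joints_used: int
    converged: bool


def rotation_y_matrix(theta_deg: float) -> np.ndarray:
    """3×3 rotation about the vertical axis.

    Convention: (x, y, z) ↦ (x cosθ + z sinθ, y, −x sinθ + z cosθ), so a +90°
    rotation maps the +x axis onto −z.
    """
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotate_y(seq: SkeletonSequence, theta: float) -> SkeletonSequence:
    """Rotate every present joint position about the y axis by *theta* degrees."""
    R = rotation_y_matrix(theta)
    return seq.with_positions(seq.positions @ R.T)


def translate(seq: SkeletonSequence, T) -> SkeletonSequence:
    """Shift every present joint position by the 3-vector *T* (meters)."""
    T = np.asarray(T, dtype=float)
    if T.shape != (3,):
        raise ValueError(f"T must be a 3-vector, got shape {T.shape}")
    return seq.with_positions(seq.positions + T)


def apply_alignment(seq: SkeletonSequence, params: AlignmentParams) -> SkeletonSequence:
    """Register a side-view sequence: rotate by θ, then translate by T."""
    return translate(rotate_y(seq, params.theta), params.T)


def spatial_error(a: SkeletonFrame, b: SkeletonFrame) -> tuple[float, int]:
    """Summed Euclidean distance over joints present in *both* frames.

    Returns ``(e_spatial, n_used)``; raises when the frames share no present
    joints, since the score is then undefined.
    """
    if set(a.joints) != set(b.joints):
        raise DegenerateGeometryError("frames do not share a joint catalog")
    total = 0.0
    n = 0
    for name, oa in a.joints.items():
        ob = b.joints[name]
        if oa.present and ob.present:
            total += float(np.linalg.norm(oa.xyz - ob.xyz))
            n += 1
    if n == 0:
        raise DegenerateGeometryError("no mutually present joints; score undefined")
    return total, n


def _window_arrays(front: SkeletonSequence, side: SkeletonSequence, window):
    """Stacked mutually-present positions over a frame-index window."""
    lo, hi = window
    sl = slice(lo - front.start_index, hi - front.start_index)
    sl2 = slice(lo - side.start_index, hi - side.start_index)
    fp, sp = front.positions[sl], side.positions[sl2]
    mask = front.present[sl] & side.present[sl2]
    if fp.shape != sp.shape:
        raise DegenerateGeometryError("window exceeds one of the streams")
    return fp[mask], sp[mask], mask


def optimize_alignment(
    front: SkeletonSequence,
    side: SkeletonSequence,
    window: tuple[int, int] | None = None,
    nominal_theta: float = 90.0,
    grid_halfwidth: float = 15.0,
    grid_step: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> AlignmentResult:
    """Estimate (T*, θ*) registering *side* onto *front*.

    Coarse-to-fine, deterministic: θ is scanned over ``nominal_theta ±
    grid_halfwidth`` in steps of *grid_step* with the translation solved in
    closed form at each angle (mean per-joint difference, which minimizes the
    summed *squared* distance and is the standard least-squares centroid
    shift); the best grid angle is then refined by bounded derivative-free
    scalar minimization.

    *window* is a ``(lo, hi)`` frame-index range (half-open); default is the
    full common range.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 mutually visible joint samples in the window.
    """
    if window is None:
        lo = max(front.start_index, side.start_index)
        hi = min(front.start_index + front.frame_count, side.start_index + side.frame_count)
        window = (lo, hi)
    if window[1] <= window[0]:
        raise DegenerateGeometryError("empty alignment window")
    fpts, spts, mask = _window_arrays(front, side, window)
    if fpts.shape[0] < 3:
        raise DegenerateGeometryError(
            f"only {fpts.shape[0]} mutually visible joint samples; need >= 3"
        )
    n_joints_used = int(np.any(mask, axis=0).sum())

    def score(theta: float) -> tuple[float, np.ndarray]:
        R = rotation_y_matrix(theta)
        rotated = spts @ R.T
        T = (fpts - rotated).mean(axis=0)
        e = float(np.linalg.norm(fpts - (rotated + T), axis=1).sum())
        return e, T

    grid = nominal_theta + np.arange(-grid_halfwidth, grid_halfwidth + grid_step / 2, grid_step)
    errs = [score(t)[0] for t in grid]
    best = int(np.argmin(errs))
    t0 = float(grid[best])

    res = minimize_scalar(
        lambda t: score(t)[0],
        bounds=(t0 - grid_step, t0 + grid_step),
        method="bounded",
        options={"maxiter": max_iter, "xatol": tol},
    )
    theta_star = float(res.x) if res.fun <= errs[best] else t0
    e_star, T_star = score(theta_star)
    return AlignmentResult(
        params=AlignmentParams(T=tuple(T_star), theta=theta_star),
        e_spatial=e_star,
        n_joints_used=n_joints_used,
        converged=bool(getattr(res, "success", True)),
    )
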