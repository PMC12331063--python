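"""End-to-end dual-view fusion pipeline.

Stage order per session: spatial registration of the side view onto the front
frame (Y-rotation + translation over a still calibration window) → temporal
registration (Pareto offset selection on depth disagreement) → depth-bias
calibration (signed front−side residual vs height) → per-frame combination
with Kalman gap-filling.

The combination rule reflects which camera is trustworthy for which axis:
x and y come from the frontal view, depth z from the registered side view.
When a joint is visible only frontally its depth is reconciled through the
fitted bias model; when visible only from the side, the inserted value's
depth gets the signed per-joint discrepancy adjustment ``z + α·e_d``; when
invisible in both views the per-joint constant-velocity filter bridges the
gap.  Every fused present joint carries exactly one provenance tag.

Observed joints keep their raw combined coordinates by default: with the
small stabilizing process noise the filter is deliberately sluggish, which is
ideal for coasting through occlusions but lags fast arm motion, so smoothing
of observed joints is opt-in (``kalman_smooth_output``).

Ablation switches reproduce the three pipeline lesions studied for the
method: ``kalman_on=False`` fills both-view gaps with the last held value,
``regression_on=False`` keeps raw front depths, ``sync_on=False`` pairs
frames by nearest timestamp (no offset compensation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .depth import (
    DepthBiasModel,
    DepthDiscrepancy,
    correct_depth,
    depth_discrepancy,
    fit_depth_bias,
)
from .errors import ConfigError, InsufficientOverlapError
from .geometry import AlignmentParams, AlignmentResult, apply_alignment, optimize_alignment
from .kalman import JointTracker, KalmanConfig, NoiseModel
from .skeleton import SkeletonFrame, SkeletonSequence, StreamMetadata
from .temporal import CandidateScore, OffsetPair, ParetoResult, synchronize

__all__ = [
    "FusionConfig",
    "SessionCalibration",
    "FusedSkeleton",
    "calibrate_session",
    "combine_frames",
    "fuse_streams",
]

TAG_FRONT = "front"
TAG_SIDE = "side+aEd"
TAG_KALMAN = "kalman"
_TAGS = (TAG_FRONT, TAG_SIDE, TAG_KALMAN)


@dataclass(frozen=True)
class FusionConfig:
    """Session-level knobs of the fusion pipeline.

    ``calibration_window`` is a (lo, hi) frame-index range over the
    stream-initial still segment; ``alpha`` scales the signed depth
    adjustment of side-inserted joints; the three ablation switches lesion
    individual pipeline stages.
    """

    alpha: float = 1.0
    visibility_threshold: float = 0.5
    calibration_window: tuple[int, int] = (40, 90)
    nominal_theta: float = 90.0
    temporal_half_window: int = 60
    # accuracy end of the Pareto front by default; the cost objective still
    # resolves the (dt_f, dt_s) degeneracy through the selection tie-break
    tradeoff: float = 1.0
    kalman_on: bool = True
    regression_on: bool = True
    sync_on: bool = True
    kalman_smooth_output: bool = False
    max_gap: int = 30
    q: float = 1e-6
    default_sigma: float = 0.01
    min_overlap: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.visibility_threshold <= 1:
            raise ConfigError("visibility_threshold must be in [0, 1]")
        if not 0 <= self.tradeoff <= 1:
            raise ConfigError("tradeoff must be in [0, 1]")
        lo, hi = self.calibration_window
        if hi <= lo:
            raise ConfigError("calibration_window must be a nonempty (lo, hi) range")


@dataclass(frozen=True)
class SessionCalibration:
    """Fitted per-session registration bundle, reused across frames."""

    alignment: AlignmentResult
    pareto: ParetoResult | None
    bias: DepthBiasModel
    discrepancy: DepthDiscrepancy
    noise: NoiseModel

    @property
    def offset_difference(self) -> int:
        if self.pareto is None:
            return 0
        return self.pareto.selected.offsets.difference

    # ------------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        a = self.alignment
        d = {
            "alignment": {
                "theta": a.params.theta,
                "T": list(a.params.T),
                "e_spatial": a.e_spatial,
                "n_joints_used": a.n_joints_used,
                "converged": a.converged,
                "composition": "rotate_then_translate",
            },
            "bias": {
                "k_e": self.bias.k_e,
                "b_e": self.bias.b_e,
                "calibration_window": list(self.bias.calibration_window or ()),
                "n_samples": self.bias.n_samples,
                "rmse": self.bias.rmse,
            },
            "discrepancy": {
                "e_d_total": self.discrepancy.e_d_total,
                "per_joint_signed": dict(self.discrepancy.per_joint_signed),
            },
            "noise": {"sigma2": list(self.noise.sigma2), "q": self.noise.q},
        }
        if self.pareto is not None:
            sel = self.pareto.selected
            d["temporal"] = {
                "selected": {
                    "dt_f": sel.offsets.dt_f,
                    "dt_s": sel.offsets.dt_s,
                    "e_sync": sel.e_sync,
                    "cost": sel.cost,
                },
                "front_size": len(self.pareto.front_set),
                "front": [
                    {
                        "dt_f": c.offsets.dt_f,
                        "dt_s": c.offsets.dt_s,
                        "e_sync": c.e_sync,
                        "cost": c.cost,
                    }
                    for c in self.pareto.front_set
                ],
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionCalibration":
        a = d["alignment"]
        alignment = AlignmentResult(
            params=AlignmentParams(T=tuple(a["T"]), theta=a["theta"]),
            e_spatial=a["e_spatial"],
            n_joints_used=a["n_joints_used"],
            converged=a["converged"],
        )
        b = d["bias"]
        bias = DepthBiasModel(
            k_e=b["k_e"],
            b_e=b["b_e"],
            calibration_window=tuple(b["calibration_window"]) or None,
            n_samples=b.get("n_samples", 0),
            rmse=b.get("rmse", 0.0),
        )
        disc = DepthDiscrepancy(
            per_joint_signed=dict(d["discrepancy"]["per_joint_signed"]),
            e_d_total=d["discrepancy"]["e_d_total"],
        )
        noise = NoiseModel(sigma2=tuple(d["noise"]["sigma2"]), q=d["noise"]["q"])
        pareto = None
        if "temporal" in d:
            front = tuple(
                CandidateScore(OffsetPair(c["dt_f"], c["dt_s"]), c["e_sync"], c["cost"])
                for c in d["temporal"]["front"]
            )
            s = d["temporal"]["selected"]
            pareto = ParetoResult(
                front_set=front,
                selected=CandidateScore(OffsetPair(s["dt_f"], s["dt_s"]), s["e_sync"], s["cost"]),
            )
        return cls(alignment, pareto, bias, disc, noise)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SessionCalibration":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


@dataclass(frozen=True)
class FusedSkeleton:
    """Fused stream plus per-joint provenance and embedded calibration.

    ``provenance`` is a (frames × joints) object array holding one tag from
    {"front", "side+aEd", "kalman"} for every present fused joint and None
    for absent ones.
    """

    sequence: SkeletonSequence
    provenance: np.ndarray
    calibration: SessionCalibration


def _clip_window(cfg_window, *seqs) -> tuple[int, int]:
    lo = max([cfg_window[0]] + [s.start_index for s in seqs])
    hi = min([cfg_window[1]] + [s.start_index + s.frame_count for s in seqs])
    if hi <= lo:
        raise ConfigError(
            f"calibration window {cfg_window} does not intersect the streams"
        )
    return lo, hi


def _window_noise(front: SkeletonSequence, window: tuple[int, int], cfg: FusionConfig) -> NoiseModel:
    """Average per-axis variance over joints fully present in the still window."""
    lo, hi = window
    sl = slice(lo - front.start_index, hi - front.start_index)
    pres = front.present[sl]
    full = pres.all(axis=0) & (pres.shape[0] >= 30)
    if not full.any():
        s2 = cfg.default_sigma**2
        return NoiseModel(sigma2=(s2, s2, s2), q=cfg.q)
    var = front.positions[sl][:, full, :].var(axis=0, ddof=1).mean(axis=0)
    return NoiseModel(sigma2=tuple(float(v) for v in var), q=cfg.q)


def calibrate_session(
    front: SkeletonSequence,
    side: SkeletonSequence,
    cfg: FusionConfig | None = None,
) -> SessionCalibration:
    """Fit the full session calibration on the still calibration window.

    Spatial registration runs first (the window is motionless, so a residual
    time offset cannot corrupt it), then temporal offset selection on the
    registered streams, then the depth-bias fit on temporally paired frames.
    Deterministic for fixed inputs and config.
    """
    cfg = cfg or FusionConfig()
    window = _clip_window(cfg.calibration_window, front, side)
    alignment = optimize_alignment(front, side, window, nominal_theta=cfg.nominal_theta)
    side_reg = apply_alignment(side, alignment.params)

    pareto: ParetoResult | None = None
    if cfg.sync_on:
        pareto = synchronize(
            front,
            side_reg,
            half_window=cfg.temporal_half_window,
            tradeoff=cfg.tradeoff,
            min_overlap=cfg.min_overlap,
        )
    d = pareto.selected.offsets.difference if pareto is not None else 0

    front_p, side_p, lo = _paired_views(front, side_reg, d)
    pair_window = (
        max(window[0], front_p.start_index),
        min(window[1], front_p.start_index + front_p.frame_count),
    )
    bias = fit_depth_bias(front_p, side_p, pair_window)

    if cfg.regression_on:
        corrected = front_p.positions.copy()
        corrected[:, :, 2] = correct_depth(corrected[:, :, 2], corrected[:, :, 1], bias)
        front_for_ed = front_p.with_positions(corrected)
    else:
        front_for_ed = front_p
    disc = depth_discrepancy(front_for_ed, side_p, pair_window)
    noise = _window_noise(front, window, cfg)
    return SessionCalibration(alignment, pareto, bias, disc, noise)


def _paired_views(front: SkeletonSequence, side_reg: SkeletonSequence, d: int):
    """Trim both streams to the overlap pairing front row u with side row u+d.

    Both returned sequences share the front stream's frame indexing over the
    overlap, so downstream windowed operations line up by construction.
    """
    nf, ns = front.frame_count, side_reg.frame_count
    lo = max(0, -d)
    hi = min(nf, ns - d)
    if hi <= lo:
        raise InsufficientOverlapError(f"offset difference {d} leaves no overlap")
    fsub = SkeletonSequence(
        front.view, front.frame_rate, front.catalog,
        front.positions[lo:hi].copy(), front.present[lo:hi].copy(),
        front.visibility[lo:hi].copy(), front.start_index + lo, front.metadata,
    )
    ssub = SkeletonSequence(
        side_reg.view, side_reg.frame_rate, side_reg.catalog,
        side_reg.positions[lo + d:hi + d].copy(), side_reg.present[lo + d:hi + d].copy(),
        side_reg.visibility[lo + d:hi + d].copy(), front.start_index + lo, side_reg.metadata,
    )
    return fsub, ssub, lo


def combine_frames(
    front_frame: SkeletonFrame,
    side_frame_registered: SkeletonFrame,
    bias: DepthBiasModel,
    e_d: DepthDiscrepancy,
    trackers: dict[str, JointTracker],
    cfg: FusionConfig | None = None,
) -> tuple[SkeletonFrame, dict[str, str]]:
    """Fuse one time-registered frame pair; returns (frame, provenance map).

    Stateless apart from the supplied trackers, which are advanced one step
    per joint.  With ``kalman_on=False`` a joint absent in both views stays
    absent (single-frame semantics; stream-level last-held-value filling is
    the fusion loop's job).
    """
    cfg = cfg or FusionConfig()
    fused: dict[str, object] = {}
    prov: dict[str, str] = {}
    from .skeleton import JointObservation  # local import to avoid cycle at module load

    for name, fobs in front_frame.joints.items():
        sobs = side_frame_registered.joints[name]
        tracker = trackers.setdefault(name, JointTracker(KalmanConfig(max_gap=cfg.max_gap)))
        e_d_joint = e_d.per_joint_signed.get(name, 0.0)
        value, tag = _fuse_joint(fobs, sobs, bias, e_d_joint, cfg)
        if value is not None:
            filtered = tracker.step(value)
            if cfg.kalman_on and cfg.kalman_smooth_output and filtered is not None:
                value = filtered
            fused[name] = JointObservation(tuple(value), 1.0, True)
            prov[name] = tag
        else:
            if cfg.kalman_on:
                pos = tracker.step(None)
                if pos is not None:
                    fused[name] = JointObservation(tuple(pos), 0.0, True)
                    prov[name] = TAG_KALMAN
                    continue
            fused[name] = JointObservation((np.nan,) * 3, 0.0, False)
    frame = SkeletonFrame(front_frame.frame_index, front_frame.timestamp, fused)
    return frame, prov


def _fuse_joint(fobs, sobs, bias, e_d_joint, cfg):
    """Per-joint combination rule; returns (3-vector | None, tag)."""
    if fobs.present and sobs.present:
        f, s = fobs.xyz, sobs.xyz
        return np.array([f[0], f[1], s[2]]), TAG_FRONT
    if fobs.present:
        f = fobs.xyz.copy()
        if cfg.regression_on:
            f[2] = correct_depth(f[2], f[1], bias)
        return f, TAG_FRONT
    if sobs.present:
        s = sobs.xyz.copy()
        s[2] += cfg.alpha * e_d_joint
        return s, TAG_SIDE
    return None, TAG_KALMAN


def fuse_streams(
    front: SkeletonSequence,
    side: SkeletonSequence,
    cfg: FusionConfig | None = None,
    calibration: SessionCalibration | None = None,
) -> FusedSkeleton:
    """Run the full pipeline and return the fused stream.

    The fused sequence covers exactly the temporal overlap of the two streams
    after the selected offsets and inherits the front stream's frame indexing
    (frame u of the fused output corresponds to front frame u).
    """
    cfg = cfg or FusionConfig()
    if front.frame_rate != side.frame_rate:
        raise ConfigError(
            f"frame-rate mismatch: front {front.frame_rate} Hz vs side {side.frame_rate} Hz"
        )
    if front.catalog != side.catalog:
        raise ConfigError("streams use different joint catalogs")
    if calibration is None:
        calibration = calibrate_session(front, side, cfg)

    side_reg = apply_alignment(side, calibration.alignment.params)
    d = calibration.offset_difference if cfg.sync_on else 0
    front_p, side_p, lo = _paired_views(front, side_reg, d)

    T, J = front_p.frame_count, len(front_p.catalog)
    kcfg = KalmanConfig(dt=front.dt, max_gap=cfg.max_gap)
    trackers = [JointTracker(kcfg, calibration.noise) for _ in range(J)]
    e_d_vec = np.array(
        [calibration.discrepancy.per_joint_signed.get(nm, 0.0) for nm in front_p.catalog]
    )

    out_pos = np.full((T, J, 3), np.nan)
    out_pres = np.zeros((T, J), dtype=bool)
    prov = np.full((T, J), None, dtype=object)
    last_held = np.full((J, 3), np.nan)

    fp, fm = front_p.positions, front_p.present
    sp, sm = side_p.positions, side_p.present
    fz_corr = fp[:, :, 2].copy()
    if cfg.regression_on:
        fz_corr = correct_depth(fp[:, :, 2], fp[:, :, 1], calibration.bias)

    for t in range(T):
        for j in range(J):
            if fm[t, j] and sm[t, j]:
                value = np.array([fp[t, j, 0], fp[t, j, 1], sp[t, j, 2]])
                tag = TAG_FRONT
            elif fm[t, j]:
                value = np.array([fp[t, j, 0], fp[t, j, 1], fz_corr[t, j]])
                tag = TAG_FRONT
            elif sm[t, j]:
                value = sp[t, j].copy()
                value[2] += cfg.alpha * e_d_vec[j]
                tag = TAG_SIDE
            else:
                value = None
                tag = TAG_KALMAN

            if value is not None:
                filtered = trackers[j].step(value) if cfg.kalman_on else None
                out = filtered if (cfg.kalman_smooth_output and filtered is not None) else value
                out_pos[t, j] = out
                out_pres[t, j] = True
                prov[t, j] = tag
                last_held[j] = out
            else:
                if cfg.kalman_on:
                    pos = trackers[j].step(None)
                    if pos is not None:
                        out_pos[t, j] = pos
                        out_pres[t, j] = True
                        prov[t, j] = TAG_KALMAN
                elif np.all(np.isfinite(last_held[j])):
                    out_pos[t, j] = last_held[j]
                    out_pres[t, j] = True
                    prov[t, j] = TAG_KALMAN

    fused_seq = SkeletonSequence(
        "fused",
        front.frame_rate,
        front_p.catalog,
        out_pos,
        out_pres,
        out_pres.astype(float),
        front_p.start_index,
        StreamMetadata(source="fused"),
    )
    return FusedSkeleton(sequence=fused_seq, provenance=prov, calibration=calibration)
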