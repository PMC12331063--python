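"""Skeleton data model and landmark-stream I/O.

A :class:`SkeletonSequence` is the package-wide container for a per-view stream
of timestamped 3-D joint observations, the output contract of any markerless
pose-estimation backend.  Coordinates follow a single project-wide right-handed
convention: *x* lateral (subject's left–right), *y* vertical (up), *z* depth
along the front camera's optical axis.  Depth is the least reliable axis of
single-view pose estimation and is the quantity the rest of the package
corrects.

Streams are fixed-rate (default 30 Hz); variable-rate input is rejected rather
than resampled, because temporal registration operates in whole-frame offsets.

File format: UTF-8 CSV with header ``frame,time,joint,x,y,z,visibility``.
Missing joints are serialized with empty ``x,y,z`` fields and visibility 0 —
a missing joint is never encoded as a zero position.  An equivalent JSON-Lines
dialect (one frame object per line, identical field names) is also supported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import AbsentJointError, ConfigError, ParseError, StructuralError

__all__ = [
    "DEFAULT_CATALOG",
    "BODY13",
    "JointObservation",
    "SkeletonFrame",
    "SkeletonSequence",
    "StreamMetadata",
    "Violation",
    "read_landmark_stream",
    "write_landmark_stream",
    "validate_sequence",
]

# 33-landmark full-body catalog of the pose backend (BlazePose-style naming).
DEFAULT_CATALOG: tuple[str, ...] = (
    "nose",
    "left_eye_inner", "left_eye", "left_eye_outer",
    "right_eye_inner", "right_eye", "right_eye_outer",
    "left_ear", "right_ear",
    "mouth_left", "mouth_right",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_pinky", "right_pinky",
    "left_index", "right_index",
    "left_thumb", "right_thumb",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
    "left_heel", "right_heel",
    "left_foot_index", "right_foot_index",
)

# Compact catalog used by the synthetic rig: head reference plus the upper- and
# lower-limb joints the exercises move.
BODY13: tuple[str, ...] = (
    "head",
    "right_shoulder", "left_shoulder",
    "right_elbow", "left_elbow",
    "right_wrist", "left_wrist",
    "right_hip", "left_hip",
    "right_knee", "left_knee",
    "right_ankle", "left_ankle",
)

_CSV_COLUMNS = ["frame", "time", "joint", "x", "y", "z", "visibility"]


@dataclass(frozen=True)
class StreamMetadata:
    """Provenance and unit information for a landmark file.

    ``units_scale`` is the multiplier applied on read to convert stored
    coordinates to meters (1.0 for metric files, 0.001 for millimeters); it is
    the explicit knob covering backends that emit normalized rather than
    metric coordinates.
    """

    source: str = ""
    units_scale: float = 1.0
    coordinate_convention: str = "RH: x right, y up (vertical), z toward front camera"

    def __post_init__(self) -> None:
        if not self.units_scale > 0:
            raise ConfigError(f"units_scale must be > 0, got {self.units_scale}")


@dataclass(frozen=True)
class JointObservation:
    """One joint in one frame: position (m), visibility in [0, 1], presence."""

    position: tuple[float, float, float]
    visibility: float = 1.0
    present: bool = True

    @property
    def xyz(self) -> np.ndarray:
        """Guarded position accessor; raises if the joint is absent."""
        if not self.present:
            raise AbsentJointError("position of an absent joint was dereferenced")
        return np.asarray(self.position, dtype=float)


@dataclass(frozen=True)
class SkeletonFrame:
    """One time sample: every catalog joint has an entry (possibly absent)."""

    frame_index: int
    timestamp: float
    joints: dict[str, JointObservation]

    def present_joints(self) -> list[str]:
        return [j for j, o in self.joints.items() if o.present]


class SkeletonSequence:
    """Fixed-rate stream of skeleton frames for one view.

    Backed by dense arrays — ``positions`` of shape (T, J, 3) with NaN where a
    joint is absent, a boolean ``present`` mask (T, J) and ``visibility``
    (T, J) — so geometric and temporal operations vectorize.  ``frames``
    materializes the per-frame mapping view on demand.
    """

    def __init__(
        self,
        view: str,
        frame_rate: float,
        catalog: Sequence[str],
        positions: np.ndarray,
        present: np.ndarray,
        visibility: np.ndarray | None = None,
        start_index: int = 0,
        metadata: StreamMetadata | None = None,
    ) -> None:
        if view not in ("front", "side", "fused", "truth"):
            raise ConfigError(f"unknown view label {view!r}")
        if not frame_rate > 0:
            raise ConfigError(f"frame_rate must be > 0, got {frame_rate}")
        catalog = tuple(catalog)
        if len(set(catalog)) != len(catalog):
            raise ConfigError("joint catalog contains duplicate identifiers")
        positions = np.asarray(positions, dtype=float)
        present = np.asarray(present, dtype=bool)
        if positions.ndim != 3 or positions.shape[1:] != (len(catalog), 3):
            raise ConfigError(
                f"positions must have shape (T, {len(catalog)}, 3), got {positions.shape}"
            )
        if present.shape != positions.shape[:2]:
            raise ConfigError("present mask shape mismatch")
        if visibility is None:
            visibility = present.astype(float)
        visibility = np.asarray(visibility, dtype=float)
        if visibility.shape != present.shape:
            raise ConfigError("visibility shape mismatch")
        self.view = view
        self.frame_rate = float(frame_rate)
        self.catalog = catalog
        self.positions = positions
        self.present = present
        self.visibility = visibility
        self.start_index = int(start_index)
        self.metadata = metadata or StreamMetadata()
        # absent joints carry NaN so they can never silently leak into math
        self.positions[~self.present] = np.nan

    # ------------------------------------------------------------------ views
    @property
    def frame_count(self) -> int:
        return self.positions.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def frame_indices(self) -> np.ndarray:
        return self.start_index + np.arange(self.frame_count)

    @property
    def timestamps(self) -> np.ndarray:
        return self.frame_indices * self.dt

    def joint_index(self, joint: str) -> int:
        try:
            return self.catalog.index(joint)
        except ValueError:
            raise KeyError(f"joint {joint!r} not in catalog") from None

    def frame(self, i: int) -> SkeletonFrame:
        joints = {}
        for j, name in enumerate(self.catalog):
            p = self.present[i, j]
            pos = tuple(self.positions[i, j]) if p else (np.nan,) * 3
            joints[name] = JointObservation(pos, float(self.visibility[i, j]), bool(p))
        return SkeletonFrame(int(self.frame_indices[i]), float(self.timestamps[i]), joints)

    @property
    def frames(self) -> list[SkeletonFrame]:
        return [self.frame(i) for i in range(self.frame_count)]

    def __len__(self) -> int:
        return self.frame_count

    def __iter__(self) -> Iterator[SkeletonFrame]:
        return iter(self.frames)

    # ------------------------------------------------------------ construction
    @classmethod
    def from_frames(
        cls,
        view: str,
        frame_rate: float,
        frames: Iterable[SkeletonFrame],
        catalog: Sequence[str] | None = None,
        metadata: StreamMetadata | None = None,
    ) -> "SkeletonSequence":
        frames = list(frames)
        if catalog is None:
            catalog = tuple(frames[0].joints) if frames else DEFAULT_CATALOG
        catalog = tuple(catalog)
        T, J = len(frames), len(catalog)
        pos = np.full((T, J, 3), np.nan)
        pres = np.zeros((T, J), dtype=bool)
        vis = np.zeros((T, J))
        for i, fr in enumerate(frames):
            for j, name in enumerate(catalog):
                obs = fr.joints.get(name)
                if obs is None:
                    continue
                vis[i, j] = obs.visibility
                if obs.present:
                    pres[i, j] = True
                    pos[i, j] = obs.position
        start = frames[0].frame_index if frames else 0
        seq = cls(view, frame_rate, catalog, pos, pres, vis, start, metadata)
        # validate index contiguity of the supplied frames
        idx = np.array([fr.frame_index for fr in frames])
        if len(idx) and not np.array_equal(idx, start + np.arange(T)):
            raise StructuralError("frame indices are not contiguous and increasing by 1")
        return seq

    def copy(self) -> "SkeletonSequence":
        return SkeletonSequence(
            self.view,
            self.frame_rate,
            self.catalog,
            self.positions.copy(),
            self.present.copy(),
            self.visibility.copy(),
            self.start_index,
            self.metadata,
        )

    def with_positions(self, positions: np.ndarray, view: str | None = None) -> "SkeletonSequence":
        """New sequence sharing masks/metadata with replaced coordinates."""
        return SkeletonSequence(
            view or self.view,
            self.frame_rate,
            self.catalog,
            np.asarray(positions, dtype=float).copy(),
            self.present.copy(),
            self.visibility.copy(),
            self.start_index,
            self.metadata,
        )


@dataclass(frozen=True)
class Violation:
    """One invariant violation, naming the frame and joint concerned."""

    frame_index: int | None
    joint: str | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = []
        if self.frame_index is not None:
            loc.append(f"frame {self.frame_index}")
        if self.joint is not None:
            loc.append(f"joint {self.joint}")
        prefix = " ".join(loc)
        return f"{prefix}: {self.message}" if prefix else self.message


def validate_sequence(seq: SkeletonSequence) -> list[Violation]:
    """Report every invariant violation in *seq* (empty list iff valid)."""
    out: list[Violation] = []
    if not seq.frame_rate > 0:
        out.append(Violation(None, None, f"frame_rate must be > 0, got {seq.frame_rate}"))
    bad_vis = (seq.visibility < 0) | (seq.visibility > 1)
    for i, j in zip(*np.nonzero(bad_vis)):
        out.append(
            Violation(
                int(seq.frame_indices[i]),
                seq.catalog[j],
                f"visibility {seq.visibility[i, j]} outside [0, 1]",
            )
        )
    bad_pos = seq.present & ~np.all(np.isfinite(seq.positions), axis=2)
    for i, j in zip(*np.nonzero(bad_pos)):
        out.append(
            Violation(
                int(seq.frame_indices[i]),
                seq.catalog[j],
                "present joint has non-finite position",
            )
        )
    # timestamp consistency is structural for fixed-rate streams
    ts = seq.timestamps
    expect = seq.frame_indices * seq.dt
    if not np.allclose(ts, expect, atol=1e-9):  # pragma: no cover - defensive
        out.append(Violation(None, None, "timestamps inconsistent with fixed frame rate"))
    return out


# ---------------------------------------------------------------------- I/O


def _float_repr(v: float) -> str:
    return format(v, ".17g")


def write_landmark_stream(seq: SkeletonSequence, path: str | Path, dialect: str = "csv") -> None:
    """Serialize *seq* to the landmark CSV (or JSON-Lines) dialect.

    Missing joints are written with empty coordinate fields and visibility 0,
    never as zeros.  Floats use round-trip precision so write→read is the
    identity and repeated writes are byte-identical.
    """
    path = Path(path)
    if dialect == "csv":
        lines = [",".join(_CSV_COLUMNS)]
        for i in range(seq.frame_count):
            fidx = int(seq.frame_indices[i])
            t = _float_repr(float(seq.timestamps[i]))
            for j, joint in enumerate(seq.catalog):
                if seq.present[i, j]:
                    x, y, z = (_float_repr(v) for v in seq.positions[i, j])
                    vis = _float_repr(float(seq.visibility[i, j]))
                else:
                    x = y = z = ""
                    vis = "0"
                lines.append(f"{fidx},{t},{joint},{x},{y},{z},{vis}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif dialect == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for i in range(seq.frame_count):
                joints = {}
                for j, joint in enumerate(seq.catalog):
                    if seq.present[i, j]:
                        x, y, z = (float(v) for v in seq.positions[i, j])
                        joints[joint] = {
                            "x": x, "y": y, "z": z,
                            "visibility": float(seq.visibility[i, j]),
                        }
                    else:
                        joints[joint] = {"x": None, "y": None, "z": None, "visibility": 0.0}
                rec = {
                    "frame": int(seq.frame_indices[i]),
                    "time": float(seq.timestamps[i]),
                    "joints": joints,
                }
                fh.write(json.dumps(rec) + "\n")
    else:
        raise ConfigError(f"unknown dialect {dialect!r}")


def read_landmark_stream(
    path: str | Path,
    metadata: StreamMetadata | None = None,
    view: str = "front",
    frame_rate: float = 30.0,
    visibility_threshold: float = 0.5,
    catalog: Sequence[str] | None = None,
    dialect: str = "csv",
) -> SkeletonSequence:
    """Read a landmark stream and return a validated :class:`SkeletonSequence`.

    Coordinates are scaled by ``metadata.units_scale`` into meters.  Rows whose
    visibility falls below *visibility_threshold* — and rows with empty
    coordinates — become ``present=False``.

    Raises
    ------
    ParseError
        Malformed row (names the line number).
    StructuralError
        Non-contiguous frame indices.
    """
    path = Path(path)
    metadata = metadata or StreamMetadata(source=str(path))
    if dialect == "jsonl":
        return _read_jsonl(path, metadata, view, frame_rate, visibility_threshold, catalog)
    try:
        df = pd.read_csv(path, dtype={"joint": str}, float_precision="round_trip")
    except Exception as exc:  # pandas raises many flavours on malformed input
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("frame", "time", "x", "y", "z", "visibility"):
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        # empty x/y/z fields are the legitimate missing-joint sentinel
        bad = coerced.isna() & raw.notna() if col in ("x", "y", "z") else coerced.isna()
        if bad.any():
            line = int(np.argmax(bad.to_numpy())) + 2  # +1 header, +1 1-based
            raise ParseError(f"{path}: line {line}: unparseable {col!r} field")
        df[col] = coerced
    frames_idx = df["frame"].to_numpy()
    if not np.array_equal(frames_idx, frames_idx.astype(int)):
        raise ParseError(f"{path}: non-integer frame index")
    frames_idx = frames_idx.astype(int)

    if catalog is None:
        catalog = tuple(dict.fromkeys(df["joint"]))
    catalog = tuple(catalog)
    jmap = {name: j for j, name in enumerate(catalog)}
    unknown = set(df["joint"]) - set(jmap)
    if unknown:
        raise ParseError(f"{path}: joints not in catalog: {sorted(unknown)}")

    uniq = np.unique(frames_idx)
    if len(uniq) and not np.array_equal(uniq, np.arange(uniq[0], uniq[0] + len(uniq))):
        raise StructuralError(f"{path}: non-contiguous frame indices")
    start = int(uniq[0]) if len(uniq) else 0
    T, J = len(uniq), len(catalog)
    pos = np.full((T, J, 3), np.nan)
    pres = np.zeros((T, J), dtype=bool)
    vis = np.zeros((T, J))
    rows_i = frames_idx - start
    rows_j = df["joint"].map(jmap).to_numpy()
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float) * metadata.units_scale
    v = df["visibility"].to_numpy(dtype=float)
    ok = np.all(np.isfinite(xyz), axis=1) & (v >= visibility_threshold)
    pos[rows_i, rows_j] = np.where(ok[:, None], xyz, np.nan)
    pres[rows_i, rows_j] = ok
    vis[rows_i, rows_j] = v
    return SkeletonSequence(view, frame_rate, catalog, pos, pres, vis, start, metadata)


def _read_jsonl(path, metadata, view, frame_rate, visibility_threshold, catalog):
    frames: list[SkeletonFrame] = []
    cat: tuple[str, ...] | None = tuple(catalog) if catalog else None
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                fidx, t, joints = rec["frame"], rec["time"], rec["joints"]
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if cat is None:
                cat = tuple(joints)
            obs = {}
            for name in cat:
                rj = joints.get(name, {})
                vis = float(rj.get("visibility", 0.0))
                vals = [rj.get(k) for k in ("x", "y", "z")]
                present = all(v is not None for v in vals) and vis >= visibility_threshold
                p = tuple(float(v) * metadata.units_scale for v in vals) if present else (np.nan,) * 3
                obs[name] = JointObservation(p, vis, present)
            frames.append(SkeletonFrame(int(fidx), float(t), obs))
    return SkeletonSequence.from_frames(view, frame_rate, frames, cat or (), metadata)
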