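"""Temporal registration of the two streams by Pareto offset selection.

Both streams run at one fixed frame rate, so alignment is searched over whole
integer frame shifts (Δt_f, Δt_s) applied to the front and side streams.  Each
candidate pair is scored by two competing objectives:

* ``e_sync`` — mean over overlapping frames of the summed absolute depth
  disagreement between mutually present joints (meters).  Averaging over the
  overlap keeps candidates with different overlap lengths comparable.
* ``cost`` — a dimensionless adjustment-cost proxy, by default
  ``|Δt_f| + |Δt_s|`` (buffer/latency per stream); an alternative cost model
  can be injected.

The non-dominated (Pareto) front over these two objectives is computed and a
single operating point picked by a normalized weighted trade-off with a
deterministic tie-break.  Only the *difference* Δt_s − Δt_f moves ``e_sync``;
the 2-D grid is retained and the resulting degeneracy is resolved by the cost
term and the tie-break rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import EmptyResultError, InsufficientOverlapError
from .skeleton import SkeletonSequence

__all__ = [
    "OffsetPair",
    "CandidateScore",
    "ParetoResult",
    "sync_error",
    "offset_cost",
    "pareto_front",
    "select_offsets",
    "shift_sequence",
    "search_offsets",
    "synchronize",
]


@dataclass(frozen=True)
class OffsetPair:
    """Integer frame shifts applied to the front (dt_f) and side (dt_s) streams."""

    dt_f: int
    dt_s: int

    @property
    def difference(self) -> int:
        return self.dt_s - self.dt_f

    @property
    def magnitude(self) -> int:
        return abs(self.dt_f) + abs(self.dt_s)


@dataclass(frozen=True)
class CandidateScore:
    offsets: OffsetPair
    e_sync: float
    cost: float


@dataclass(frozen=True)
class ParetoResult:
    """Non-dominated candidate set and the selected operating point."""

    front_set: tuple[CandidateScore, ...]
    selected: CandidateScore


def _depth_overlap(front: SkeletonSequence, side: SkeletonSequence, d: int):
    """Paired depth arrays for relative shift d = dt_s − dt_f.

    Pairs front frame u with side frame u + d (array-row indexing).
    """
    nf, ns = front.frame_count, side.frame_count
    lo = max(0, -d)
    hi = min(nf, ns - d)
    if hi <= lo:
        return None
    zf = front.positions[lo:hi, :, 2]
    zs = side.positions[lo + d:hi + d, :, 2]
    both = front.present[lo:hi] & side.present[lo + d:hi + d]
    return zf, zs, both


def sync_error(
    front: SkeletonSequence,
    side_aligned: SkeletonSequence,
    offsets: OffsetPair,
    min_overlap: int = 10,
) -> float:
    """Mean per-frame summed absolute depth disagreement under *offsets*.

    The side stream must already be spatially registered into the front frame.

    Raises
    ------
    InsufficientOverlapError
        Fewer than *min_overlap* overlapping frames after shifting.
    """
    pair = _depth_overlap(front, side_aligned, offsets.difference)
    if pair is None or pair[0].shape[0] < min_overlap:
        n = 0 if pair is None else pair[0].shape[0]
        raise InsufficientOverlapError(
            f"offsets {offsets} leave {n} overlapping frames (< {min_overlap})"
        )
    zf, zs, both = pair
    diff = np.where(both, np.abs(zf - zs), 0.0)
    return float(diff.sum(axis=1).mean())


def offset_cost(
    offsets: OffsetPair,
    cost_fn: Callable[[int], float] | None = None,
) -> float:
    """Adjustment cost C = C_f(Δt_f) + C_s(Δt_s); default C(dt) = |dt|."""
    f = cost_fn if cost_fn is not None else lambda dt: float(abs(dt))
    return float(f(offsets.dt_f) + f(offsets.dt_s))


def pareto_front(candidates: Sequence[CandidateScore]) -> list[CandidateScore]:
    """Exactly the candidates not dominated in (e_sync, cost).

    Dominance: another candidate is ≤ in both objectives and < in at least
    one.  Input order of survivors is preserved.  Duplicated objective pairs
    do not dominate each other, so duplicates all survive.
    """
    if not candidates:
        raise EmptyResultError("pareto_front of an empty candidate list")
    e = np.array([c.e_sync for c in candidates])
    c = np.array([c.cost for c in candidates])
    # plane-sweep in e: a candidate is dominated iff some strictly-smaller-e
    # candidate has cost <= its own, or an equal-e candidate has cost < its own
    order = np.lexsort((c, e))
    dominated = np.zeros(len(candidates), dtype=bool)
    best_c_prev = np.inf  # min cost over all strictly smaller e
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and e[order[j]] == e[order[i]]:
            j += 1
        group = order[i:j]
        group_min_c = c[group].min()
        for k in group:
            dominated[k] = c[k] > group_min_c or c[k] >= best_c_prev
        best_c_prev = min(best_c_prev, group_min_c)
        i = j
    return [cand for cand, dom in zip(candidates, dominated) if not dom]


def select_offsets(front_set: Sequence[CandidateScore], tradeoff: float = 0.5) -> CandidateScore:
    """Pick one front member by normalized weighted trade-off.

    Minimizes ``tradeoff·ê_sync + (1−tradeoff)·ĉ`` where ê, ĉ are min-max
    normalized over the front (a degenerate objective normalizes to 0).
    Ties break deterministically: smaller |Δt_f|+|Δt_s|, then smaller Δt_f.
    """
    if not front_set:
        raise EmptyResultError("select_offsets on an empty front")
    if not 0.0 <= tradeoff <= 1.0:
        raise ValueError(f"tradeoff must be in [0, 1], got {tradeoff}")
    e = np.array([c.e_sync for c in front_set])
    c = np.array([c.cost for c in front_set])

    def norm(v: np.ndarray) -> np.ndarray:
        span = v.max() - v.min()
        return (v - v.min()) / span if span > 0 else np.zeros_like(v)

    score = tradeoff * norm(e) + (1.0 - tradeoff) * norm(c)
    keys = [
        (score[i], front_set[i].offsets.magnitude, front_set[i].offsets.dt_f)
        for i in range(len(front_set))
    ]
    return front_set[min(range(len(front_set)), key=keys.__getitem__)]


def shift_sequence(seq: SkeletonSequence, dt: int) -> SkeletonSequence:
    """Apply a whole-frame shift: new frame t shows old frame t + dt.

    Frames shifted out of range are dropped, so the result has
    ``frame_count − |dt|`` frames, renumbered from the original start index.
    """
    n = seq.frame_count
    if abs(dt) >= n:
        raise EmptyResultError(f"|dt|={abs(dt)} >= frame_count={n}: empty result")
    lo, hi = max(0, dt), min(n, n + dt)
    return SkeletonSequence(
        seq.view,
        seq.frame_rate,
        seq.catalog,
        seq.positions[lo:hi].copy(),
        seq.present[lo:hi].copy(),
        seq.visibility[lo:hi].copy(),
        seq.start_index,
        seq.metadata,
    )


def search_offsets(
    front: SkeletonSequence,
    side_aligned: SkeletonSequence,
    half_window: int = 60,
    min_overlap: int = 10,
    cost_fn: Callable[[int], float] | None = None,
) -> list[CandidateScore]:
    """Score the full (2·half_window+1)² offset grid.

    ``e_sync`` depends only on the offset difference, so it is evaluated once
    per distinct difference and broadcast over the grid; the cost term is
    per-pair.  Infeasible differences (overlap below *min_overlap*) are
    dropped.
    """
    errs: dict[int, float] = {}
    for d in range(-2 * half_window, 2 * half_window + 1):
        pair = _depth_overlap(front, side_aligned, d)
        if pair is None or pair[0].shape[0] < min_overlap:
            continue
        zf, zs, both = pair
        diff = np.where(both, np.abs(zf - zs), 0.0)
        errs[d] = float(diff.sum(axis=1).mean())
    out: list[CandidateScore] = []
    for dt_f in range(-half_window, half_window + 1):
        for dt_s in range(-half_window, half_window + 1):
            d = dt_s - dt_f
            if d not in errs:
                continue
            off = OffsetPair(dt_f, dt_s)
            out.append(CandidateScore(off, errs[d], offset_cost(off, cost_fn)))
    if not out:
        raise InsufficientOverlapError("no feasible offsets within the search window")
    return out


def synchronize(
    front: SkeletonSequence,
    side_aligned: SkeletonSequence,
    half_window: int = 60,
    tradeoff: float = 0.5,
    min_overlap: int = 10,
    cost_fn: Callable[[int], float] | None = None,
) -> ParetoResult:
    """Grid search → Pareto front → trade-off selection, in one call."""
    candidates = search_offsets(front, side_aligned, half_window, min_overlap, cost_fn)
    front_set = pareto_front(candidates)
    selected = select_offsets(front_set, tradeoff)
    return ParetoResult(front_set=tuple(front_set), selected=selected)
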