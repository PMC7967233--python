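"""Multi-label fast marching: arrival times T and region labels R.

Solves the Eikonal equation ``|grad T| * F = 1`` with the first-order
upwind (Godunov) scheme on a 4-connected grid, propagating one front per
seed.  A min-heap over the narrow band yields the classic ``N log N``
single-pass solver; each pixel, once frozen, carries the label of the
seed whose front reached it first, producing a complete "stained glass"
partition of the domain.

Determinism: exact time ties are broken in raster order (lowest
``(T, row, col)`` heap key), and label ties by the lowest label, so runs
are bit-reproducible and independent of seed insertion order except
where exact ties occur.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .speedseed import SeedGrid, SpeedImage

#: Region label for pixels outside the domain or unreachable within it.
UNASSIGNED = -1

#: Chebyshev radius of the exact-initialization box around each seed.
#: First-order upwind schemes suffer a well-known accuracy loss at point
#: sources (the arrival-time surface is not smooth there); freezing seeds
#: at T=0 and seeding trial times ``T = |x - seed| / F`` over a small box
#: instead of only the four axis neighbours is the standard mitigation.
#: Axis neighbours still receive exactly ``1/F``.
SOURCE_INIT_RADIUS = 2

_FAR, _NARROW, _KNOWN = 0, 1, 2


def solve_trial_time(
    t_left: float,
    t_right: float,
    t_up: float,
    t_down: float,
    speed: float,
    h: float = 1.0,
) -> float:
    """Godunov upwind update from up to four axis-neighbour times.

    With ``a = min(t_left, t_right)`` and ``b = min(t_up, t_down)``: when
    the axis times differ by at least ``h / speed`` (or one axis has no
    finite time) the 1D update ``min(a, b) + h / speed`` applies;
    otherwise the larger root of ``(T - a)^2 + (T - b)^2 = (h / speed)^2``
    is returned.
    """
    if speed <= 0:
        raise ValueError("speed must be strictly positive")
    a = min(t_left, t_right)
    b = min(t_up, t_down)
    if a > b:
        a, b = b, a
    if math.isinf(a):
        raise ValueError("at least one neighbour time must be finite")
    rhs = h / speed
    if math.isinf(b) or b - a >= rhs:
        return a + rhs
    return 0.5 * ((a + b) + math.sqrt(2.0 * rhs * rhs - (a - b) ** 2))


@dataclass
class FMMState:
    """Mutable marching state: times, labels, status tags and the heap."""

    T: np.ndarray
    R: np.ndarray
    status: np.ndarray
    heap: list
    domain: np.ndarray
    seeds: list[tuple[int, int]]


@dataclass
class RegionSet:
    """Final partition: label image plus per-region statistics."""

    labels: np.ndarray
    region_stats: dict[int, dict]
    seeds: list[tuple[int, int]]


def initialize(
    seeds: SeedGrid | list[tuple[int, int]],
    F: SpeedImage,
    domain: np.ndarray | None = None,
) -> FMMState:
    """Set initial values: seeds known at T=0, their 4-neighbours trial.

    Each seed's 4-neighbours enter the narrow band with ``T = 1 / F`` and
    the adjacent seed's label; a neighbour shared by several seeds keeps
    the smallest time (ties: lowest seed index).  The remaining pixels of
    the :data:`SOURCE_INIT_RADIUS` box around each seed receive the
    first-order estimate ``T = dist / F`` (see the constant's note on
    point-source accuracy).  All other pixels are far with ``T = inf``.
    """
    seed_list = seeds.seeds if isinstance(seeds, SeedGrid) else list(seeds)
    if not seed_list:
        raise ValueError("seed set is empty")
    Fa = F.F
    h_, w_ = Fa.shape
    dom = (
        np.asarray(domain, dtype=bool)
        if domain is not None
        else np.ones((h_, w_), bool)
    )
    T = np.full((h_, w_), np.inf)
    R = np.full((h_, w_), UNASSIGNED, dtype=np.int64)
    status = np.full((h_, w_), _FAR, dtype=np.int8)
    heap: list = []

    for label, (r, c) in enumerate(seed_list):
        if not (0 <= r < h_ and 0 <= c < w_) or not dom[r, c]:
            raise ValueError(f"seed {(r, c)} outside domain")
        T[r, c] = 0.0
        R[r, c] = label
        status[r, c] = _KNOWN

    rad = SOURCE_INIT_RADIUS
    band: list[tuple[int, int]] = []
    for label, (r, c) in enumerate(seed_list):
        for dr in range(-rad, rad + 1):
            for dc in range(-rad, rad + 1):
                if dr == 0 and dc == 0:
                    continue
                nr, nc = r + dr, c + dc
                if not (0 <= nr < h_ and 0 <= nc < w_) or not dom[nr, nc]:
                    continue
                if status[nr, nc] == _KNOWN:
                    continue
                if abs(dr) + abs(dc) == 1:
                    t = 1.0 / Fa[nr, nc]
                else:
                    # line-averaged slowness (trapezoid) for the outer ring
                    t = (
                        math.hypot(dr, dc)
                        * (1.0 / Fa[r, c] + 1.0 / Fa[nr, nc])
                        / 2.0
                    )
                if status[nr, nc] == _FAR:
                    band.append((nr, nc))
                if t < T[nr, nc]:  # strict: ties keep the lower seed index
                    T[nr, nc] = t
                    R[nr, nc] = label
                    status[nr, nc] = _NARROW

    # Pixels with several frozen (seed) axis neighbours obey the upwind
    # quadratic, which can undercut the 1D estimate; settling this here
    # keeps the pop sequence monotone during the march.
    for nr, nc in band:
        axis = []
        for ar, ac in ((nr - 1, nc), (nr + 1, nc), (nr, nc - 1), (nr, nc + 1)):
            if (
                0 <= ar < h_
                and 0 <= ac < w_
                and dom[ar, ac]
                and status[ar, ac] == _KNOWN
            ):
                axis.append((T[ar, ac], ar, ac))
            else:
                axis.append((np.inf, ar, ac))
        if sum(math.isfinite(t) for t, _, _ in axis) >= 2:
            t = solve_trial_time(
                axis[2][0], axis[3][0], axis[0][0], axis[1][0], Fa[nr, nc]
            )
            if t < T[nr, nc]:
                T[nr, nc] = t
                best = min(a for a in axis if math.isfinite(a[0]))
                R[nr, nc] = R[best[1], best[2]]

    for nr, nc in band:
        heapq.heappush(heap, (T[nr, nc], nr, nc))

    return FMMState(T=T, R=R, status=status, heap=heap, domain=dom, seeds=seed_list)


def march(
    state: FMMState,
    F: SpeedImage,
    img: np.ndarray | None = None,
) -> tuple[RegionSet, np.ndarray]:
    """Run the forward marching loop until the narrow band is exhausted.

    Pops the minimum-time narrow-band pixel, freezes it, and recomputes
    trial times of its non-frozen 4-neighbours from their known axis
    neighbours; an improved time also re-inherits the label of the known
    stencil neighbour with the smallest time.  Stale heap entries are
    skipped on pop (lazy deletion).  Returns the region partition and the
    arrival-time matrix; per-region mean intensities are computed from
    ``img`` when given.
    """
    T, R, status, heap, dom = state.T, state.R, state.status, state.heap, state.domain
    Fa = F.F
    h_, w_ = Fa.shape
    last_popped = 0.0

    while heap:
        t, r, c = heapq.heappop(heap)
        if status[r, c] == _KNOWN:
            continue  # stale entry
        if t > T[r, c]:
            continue  # superseded by a better update
        assert t >= last_popped - 1e-9, "causality violated: non-monotone pop"
        last_popped = t
        status[r, c] = _KNOWN

        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if not (0 <= nr < h_ and 0 <= nc < w_) or not dom[nr, nc]:
                continue
            if status[nr, nc] == _KNOWN:
                continue
            axis_times = []
            for ar, ac in ((nr - 1, nc), (nr + 1, nc), (nr, nc - 1), (nr, nc + 1)):
                if (
                    0 <= ar < h_
                    and 0 <= ac < w_
                    and dom[ar, ac]
                    and status[ar, ac] == _KNOWN
                ):
                    axis_times.append((T[ar, ac], ar, ac))
                else:
                    axis_times.append((np.inf, ar, ac))
            new_t = solve_trial_time(
                axis_times[2][0],
                axis_times[3][0],
                axis_times[0][0],
                axis_times[1][0],
                Fa[nr, nc],
            )
            if new_t < T[nr, nc]:
                T[nr, nc] = new_t
                # label of the known stencil neighbour with smallest T;
                # ties resolved by raster order of the neighbour, then label
                best = min(
                    (tt, ar, ac)
                    for tt, ar, ac in axis_times
                    if math.isfinite(tt)
                )
                R[nr, nc] = R[best[1], best[2]]
                status[nr, nc] = _NARROW
                heapq.heappush(heap, (new_t, nr, nc))

    unreachable = dom & (status != _KNOWN)
    if unreachable.any():
        warnings.warn(
            f"{int(unreachable.sum())} in-domain pixels unreachable; "
            "assigned sentinel label",
            stacklevel=2,
        )
        R[unreachable] = UNASSIGNED

    R[~dom] = UNASSIGNED
    stats: dict[int, dict] = {}
    for label, (sr, sc) in enumerate(state.seeds):
        member = R == label
        count = int(member.sum())
        entry = {"seed": (sr, sc), "pixel_count": count}
        if img is not None and count:
            entry["mean_intensity"] = float(np.asarray(img, float)[member].mean())
        stats[label] = entry
    return RegionSet(labels=R, region_stats=stats, seeds=state.seeds), T


def partition(
    seeds: SeedGrid | list[tuple[int, int]],
    F: SpeedImage,
    img: np.ndarray | None = None,
    domain: np.ndarray | None = None,
) -> tuple[RegionSet, np.ndarray]:
    """Convenience wrapper: initialize then march."""
    return march(initialize(seeds, F, domain), F, img)
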