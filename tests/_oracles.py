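"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: graph shortest paths
instead of the upwind solver, exhaustive pairwise scans instead of the
rotating measurement, exhaustive partition search instead of Lloyd
iterations.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra


def dijkstra_times(F: np.ndarray, seeds) -> np.ndarray:
    """Shortest arrival times on the 8-connected pixel graph.

    Edge cost between u and v is ``step * (1/F_u + 1/F_v) / 2`` with step
    1 for axis moves and sqrt(2) for diagonal moves; the result is the
    minimum over all seed sources.
    """
    F = np.asarray(F, dtype=float)
    n, m = F.shape
    S = 1.0 / F
    idx = np.arange(n * m).reshape(n, m)
    rows, cols, w = [], [], []
    for dr, dc, step in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))):
        if dc >= 0:
            a = idx[: n - dr or None, : m - dc or None]
            b = idx[dr:, dc:]
        else:
            a = idx[: n - dr or None, -dc:]
            b = idx[dr:, :dc]
        cost = step * (S.ravel()[a.ravel()] + S.ravel()[b.ravel()]) / 2.0
        rows.append(a.ravel())
        cols.append(b.ravel())
        w.append(cost)
    g = coo_matrix(
        (np.concatenate(w), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * m, n * m),
    )
    srcs = [r * m + c for r, c in seeds]
    d = _csgraph_dijkstra(g, directed=False, indices=srcs)
    return d.min(axis=0).reshape(n, m)


def replay_pop_times(F: np.ndarray, seeds) -> list[float]:
    """Re-runs the forward marching loop independently, recording the time
    of every effective (non-stale) pop."""
    import heapq
    import math

    from fmmseg.fmm import initialize, solve_trial_time
    from fmmseg.speedseed import SpeedImage

    F = np.asarray(F, dtype=float)
    n, m = F.shape
    state = initialize(list(seeds), SpeedImage(F))
    T, heap = state.T, state.heap
    frozen = set(seeds)
    pops = []
    while heap:
        t, r, c = heapq.heappop(heap)
        if (r, c) in frozen or t > T[r, c]:
            continue
        frozen.add((r, c))
        pops.append(t)
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if not (0 <= nr < n and 0 <= nc < m) or (nr, nc) in frozen:
                continue
            ts = [
                T[ar, ac]
                if (0 <= ar < n and 0 <= ac < m and (ar, ac) in frozen)
                else math.inf
                for ar, ac in ((nr - 1, nc), (nr + 1, nc), (nr, nc - 1), (nr, nc + 1))
            ]
            nt = solve_trial_time(ts[2], ts[3], ts[0], ts[1], F[nr, nc])
            if nt < T[nr, nc]:
                T[nr, nc] = nt
                heapq.heappush(heap, (nt, nr, nc))
    return pops


def brute_long_axis(mask: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Max pairwise center-to-center distance between border pixels."""
    from scipy import ndimage

    mask = np.asarray(mask, bool)
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    border = np.argwhere(mask & ~interior).astype(float)
    best = (0.0, border[0], border[0])
    for p, q in itertools.combinations(border, 2):
        d = float(np.hypot(*(p - q)))
        if d > best[0]:
            best = (d, p, q)
    return best


def brute_short_axis(mask: np.ndarray, u: np.ndarray) -> float:
    """Max perpendicular chord by exhaustive pixel-pair scan.

    Considers every pair of mask pixels whose separation is (nearly)
    perpendicular to the long-axis direction ``u`` — within half a pixel
    of projection along ``u`` — and returns the largest perpendicular
    extent.
    """
    pts = np.argwhere(np.asarray(mask, bool)).astype(float)
    v = np.array([-u[1], u[0]])
    best = 0.0
    for p, q in itertools.combinations(pts, 2):
        d = p - q
        if abs(d @ u) <= 0.5:
            best = max(best, abs(d @ v))
    return best


def brute_two_means(points: np.ndarray, k: int = 2):
    """Optimal k=2 clustering by exhaustive partition search (n <= 8)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    best = (np.inf, None)
    for bits in range(1, 2 ** (n - 1)):  # fix point 0 in group 0: halves the search
        groups = [(bits >> i) & 1 for i in range(n)]
        if len(set(groups)) != k:
            continue
        cost = 0.0
        for g in range(k):
            sel = pts[[i for i in range(n) if groups[i] == g]]
            cost += ((sel - sel.mean(axis=0)) ** 2).sum()
        if cost < best[0]:
            best = (cost, groups)
    return best[1]


def point_in_hull(points: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Membership of query points in the convex hull of ``points``."""
    from scipy.spatial import Delaunay

    tri = Delaunay(np.asarray(points, float))
    return tri.find_simplex(np.asarray(queries, float)) >= 0


def seed_rule_oracle(G, domain, r, c, total, alpha, beta):
    """Exhaustive evaluation of the keep/shift/delete rules at one lattice
    point; returns ('delete', None) / ('shift', pos) / ('keep', (r, c))."""
    h, w = G.shape

    def local(rr, cc):
        vals = [
            G[ar, ac]
            for ar in range(max(rr - 1, 0), min(rr + 2, h))
            for ac in range(max(cc - 1, 0), min(cc + 2, w))
            if domain[ar, ac]
        ]
        return float(np.mean(vals))

    lm = local(r, c)
    if lm > beta * total:
        return "delete", None
    if lm >= alpha * total:
        neigh = [
            (local(ar, ac), (ar, ac))
            for ar in range(max(r - 1, 0), min(r + 2, h))
            for ac in range(max(c - 1, 0), min(c + 2, w))
            if (ar, ac) != (r, c) and domain[ar, ac]
        ]
        minval = min([lm] + [v for v, _ in neigh])
        if lm == minval:  # the seed itself wins exact ties
            return "shift", (r, c)
        for v, pos in neigh:  # raster order; first strict minimum wins
            if v == minval:
                return "shift", pos
    return "keep", (r, c)
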