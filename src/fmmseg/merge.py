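"""Region clustering and merging into the final nodule mask.

The fast marching partition is deliberately over-segmented (dense seeds),
so neighbouring regions often differ by less than any sensible intensity
threshold even across a true boundary.  Regions are therefore first
grouped into larger clusters with k-means on seed coordinates — seeds in
uniform areas pack closely and belong together — and merging operates on
clusters, whose mean-intensity contrast is much more pronounced.

Initial k-means centroids come from the same keep/shift/delete lattice
filter as the seed grid (pitch = ``cluster_density``), which both keeps
centroids away from boundaries and makes the whole pipeline
deterministic: no random initialization anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .config import DEFAULT_PARAMS, SegmentationParams
from .fmm import UNASSIGNED, RegionSet, partition
from .preprocess import NoduleImage
from .speedseed import (
    GradientField,
    denoise,
    generate_seed_grid,
    gradient_magnitude,
    pad_pleura,
    speed_from_gradient,
)

#: Guard (px) against the centroid-at-center singularity in the start ratio.
CENTER_EPS = 1.0


@dataclass
class ClusterSet:
    """Region→cluster assignment with per-cluster statistics.

    ``adjacency`` relates clusters sharing a 4-connected pixel boundary;
    it is symmetric and irreflexive.
    """

    cluster_of_region: dict[int, int]
    labels: np.ndarray  # cluster id per pixel, UNASSIGNED outside domain
    stats: dict[int, dict]  # id -> {mean_intensity, centroid, member_pixel_count}
    adjacency: dict[int, set[int]]


@dataclass
class SegmentationMask:
    """Binary nodule mask plus the merge trace that produced it."""

    mask: np.ndarray
    merged_cluster_ids: set[int]
    trace: list[dict] = field(default_factory=list)
    start_cluster: int | None = None


def init_centroids(
    grad: GradientField,
    mask: np.ndarray | None = None,
    cluster_density: int = 7,
    alpha: float = 1.0,
    beta: float = 2.0,
) -> list[tuple[int, int]]:
    """Initial k-means centroids from the seed-grid filter at a wider pitch."""
    if cluster_density < 3:
        raise ValueError("cluster_density must be >= 3")
    grid = generate_seed_grid(
        grad, mask, seed_distance=cluster_density, alpha=alpha, beta=beta
    )
    if len(grid.seeds) == 1:
        warnings.warn("single centroid: merging degenerates to one cluster")
    return grid.seeds


def cluster_regions(
    regions: RegionSet,
    centroids: list[tuple[int, int]],
    img: np.ndarray,
) -> ClusterSet:
    """Group regions into clusters by k-means over seed coordinates.

    k equals the number of supplied centroids and the centroids are used
    as the (deterministic) initialization; each region is assigned wholly
    to the cluster of its seed.  Cluster statistics are recomputed from
    member pixels.  Empty clusters are dropped and ids reindexed.
    """
    if not centroids:
        raise ValueError("need at least one centroid")
    seeds = np.asarray(regions.seeds, dtype=float)
    k = min(len(centroids), len(seeds))
    init = np.asarray(centroids[:k], dtype=float)
    if k == 1:
        seed_cluster = np.zeros(len(seeds), dtype=int)
    else:
        km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=100, tol=1e-4)
        seed_cluster = km.fit_predict(seeds)

    cluster_of_region = {lab: int(seed_cluster[lab]) for lab in range(len(seeds))}

    R = regions.labels
    L = np.full_like(R, UNASSIGNED)
    inside = R != UNASSIGNED
    lut = np.full(len(seeds), UNASSIGNED, dtype=np.int64)
    for lab, cid in cluster_of_region.items():
        lut[lab] = cid
    L[inside] = lut[R[inside]]

    # drop empty clusters, reindex densely
    present = sorted({int(c) for c in np.unique(L[inside])})
    remap = {old: new for new, old in enumerate(present)}
    L[inside] = np.vectorize(remap.get)(L[inside]) if present else L[inside]
    cluster_of_region = {
        lab: remap[cid] for lab, cid in cluster_of_region.items() if cid in remap
    }

    img = np.asarray(img, dtype=float)
    stats: dict[int, dict] = {}
    for cid in range(len(present)):
        member = L == cid
        rr, cc = np.nonzero(member)
        stats[cid] = {
            "mean_intensity": float(img[member].mean()),
            "centroid": (float(rr.mean()), float(cc.mean())),
            "member_pixel_count": int(member.sum()),
        }

    adjacency: dict[int, set[int]] = {cid: set() for cid in range(len(present))}
    for a, b in _touching_pairs(L):
        adjacency[a].add(b)
        adjacency[b].add(a)

    return ClusterSet(
        cluster_of_region=cluster_of_region, labels=L, stats=stats, adjacency=adjacency
    )


def _touching_pairs(L: np.ndarray):
    """Unordered pairs of distinct cluster ids sharing a 4-connected edge."""
    pairs = set()
    for da, db in ((L[:-1, :], L[1:, :]), (L[:, :-1], L[:, 1:])):
        diff = (da != db) & (da != UNASSIGNED) & (db != UNASSIGNED)
        for a, b in zip(da[diff].ravel(), db[diff].ravel()):
            pairs.add((min(int(a), int(b)), max(int(a), int(b))))
    return pairs


def select_start_cluster(
    clusters: ClusterSet, image_shape: tuple[int, int]
) -> int:
    """Pick the cluster most likely to lie inside the nodule.

    The crop is nodule-centered, but the brightest cluster is not always
    nodular (pleural remnants) and the central cluster is not either
    (cavitary nodules), so both cues are combined: the winner maximizes
    ``mean_intensity / (distance of centroid to image center + 1)``.
    Ties go to the lower cluster id.
    """
    if not clusters.stats:
        raise ValueError("no clusters")
    h, w = image_shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    best_id, best_ratio = None, -np.inf
    for cid in sorted(clusters.stats):
        s = clusters.stats[cid]
        d = float(np.linalg.norm(np.asarray(s["centroid"]) - center))
        ratio = s["mean_intensity"] / (d + CENTER_EPS)
        if ratio > best_ratio + 1e-15:
            best_id, best_ratio = cid, ratio
    return int(best_id)


def merge_clusters(
    clusters: ClusterSet,
    start: int,
    mean_threshold: float = 0.15,
) -> SegmentationMask:
    """Grow the nodule mask over the cluster adjacency graph.

    Breadth-first from the start cluster: a neighbour ``j`` of an
    accepted cluster ``i`` is accepted iff ``|mean_i - mean_j| <
    mean_threshold`` (pairwise cluster means, not a running blob mean).
    A cluster rejected from one discoverer may still be accepted later
    from another.  The mask is the union of accepted clusters' pixels.
    """
    if start not in clusters.stats:
        raise ValueError("start is not a valid cluster id")
    if not 0.0 < mean_threshold < 1.0:
        raise ValueError("mean_threshold must lie in (0, 1)")

    accepted = {start}
    trace: list[dict] = []
    frontier = [start]
    while frontier:
        nxt = []
        for i in sorted(frontier):
            mi = clusters.stats[i]["mean_intensity"]
            for j in sorted(clusters.adjacency.get(i, ())):
                if j in accepted:
                    continue
                diff = abs(mi - clusters.stats[j]["mean_intensity"])
                ok = diff < mean_threshold
                trace.append(
                    {"from": i, "to": j, "diff": diff, "accepted": bool(ok)}
                )
                if ok:
                    accepted.add(j)
                    nxt.append(j)
        frontier = nxt

    mask = np.isin(clusters.labels, sorted(accepted))
    return SegmentationMask(
        mask=mask, merged_cluster_ids=accepted, trace=trace, start_cluster=start
    )


@dataclass
class SegmentationResult:
    """End-to-end output with intermediates useful for inspection."""

    mask: SegmentationMask
    regions: RegionSet
    clusters: ClusterSet
    arrival_times: np.ndarray
    speed: np.ndarray
    seeds: list[tuple[int, int]]


def segment(
    img: NoduleImage,
    params: SegmentationParams = DEFAULT_PARAMS,
    return_intermediates: bool = False,
):
    """Full pipeline: denoise → pad → gradient → speed/seeds → FMM →
    cluster → start selection → merge.

    Returns a :class:`SegmentationMask` (restricted to the lung mask when
    present), or a :class:`SegmentationResult` with intermediates when
    ``return_intermediates`` is true.  Fully deterministic for fixed
    inputs and parameters.
    """
    mask = img.lung_mask
    den = denoise(
        img.intensity,
        kappa=params.diffusion_kappa,
        iters=params.diffusion_iters,
        dt=params.diffusion_dt,
    )
    padded = pad_pleura(den, mask)
    grad = gradient_magnitude(padded, sigma=params.sigma, mask=mask)
    speed = speed_from_gradient(grad, tau=params.tau)
    seeds = generate_seed_grid(
        grad,
        mask,
        seed_distance=params.seed_distance,
        alpha=params.alpha,
        beta=params.beta,
    )
    regions, T = partition(seeds, speed, img=img.intensity, domain=mask)
    centroids = init_centroids(
        grad, mask, cluster_density=params.cluster_density,
        alpha=params.alpha, beta=params.beta,
    )
    clusters = cluster_regions(regions, centroids, img.intensity)
    start = select_start_cluster(clusters, img.intensity.shape)
    seg = merge_clusters(clusters, start, mean_threshold=params.mean_threshold)
    if mask is not None:
        seg.mask &= mask
    if not seg.mask.any():
        warnings.warn("empty segmentation mask after domain restriction")
    if return_intermediates:
        return SegmentationResult(
            mask=seg,
            regions=regions,
            clusters=clusters,
            arrival_times=T,
            speed=speed.F,
            seeds=seeds.seeds,
        )
    return seg
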