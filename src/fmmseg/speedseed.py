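"""Speed-image and seed-grid construction for the fast marching fronts.

The front speed is an inverse function of the image gradient: close to
zero at object boundaries, close to one in homogeneous tissue.  Seeds are
laid on a dense lattice and then filtered by local gradient statistics so
that fronts start only in uniform areas — a seed whose neighbourhood mean
gradient exceeds ``beta`` times the image-wide mean is deleted, one in
the intermediate band is shifted (diagonals included) to the flattest
neighbouring pixel, and one below ``alpha`` times the mean is kept as is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class NoSeedsError(ValueError):
    """No seed survives the gradient filtering: no uniform region to seed."""


@dataclass
class GradientField:
    """Gradient magnitude of the (smoothed, padded) image.

    ``total_grad_mean`` is the mean of ``G`` over the valid domain (the
    lung mask when one is present, the full image otherwise) and serves
    as the decision threshold for seed filtering.
    """

    G: np.ndarray
    total_grad_mean: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if (self.G < 0).any() or not np.isfinite(self.G).all():
            raise ValueError("gradient magnitude must be finite and non-negative")


@dataclass
class SpeedImage:
    """Per-pixel front speed in (0, 1], max-normalized to 1."""

    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if not np.isfinite(self.F).all():
            raise ValueError("speed must be finite")
        if self.F.min() <= 0:
            raise ValueError("speed must be strictly positive")


@dataclass
class SeedGrid:
    """Surviving seed coordinates plus the parameters that produced them."""

    seeds: list[tuple[int, int]]
    seed_distance: int = 3
    alpha: float = 1.0
    beta: float = 2.0
    params: dict = field(default_factory=dict)


def denoise(
    img: np.ndarray,
    kappa: float = 0.05,
    iters: int = 10,
    dt: float = 0.15,
) -> np.ndarray:
    """Perona–Malik anisotropic diffusion with exponential conductance.

    Smooths flat regions while leaving edges in place: the conductance
    ``exp(-(dI/kappa)^2)`` vanishes across strong intensity steps, so no
    flux crosses them.  ``kappa`` is in normalized-intensity units.
    """
    u = np.asarray(img, dtype=float).copy()
    for _ in range(iters):
        dn = np.zeros_like(u)
        ds = np.zeros_like(u)
        de = np.zeros_like(u)
        dw = np.zeros_like(u)
        dn[1:, :] = u[:-1, :] - u[1:, :]
        ds[:-1, :] = u[1:, :] - u[:-1, :]
        de[:, :-1] = u[:, 1:] - u[:, :-1]
        dw[:, 1:] = u[:, :-1] - u[:, 1:]
        flux = sum(d * np.exp(-((d / kappa) ** 2)) for d in (dn, ds, de, dw))
        u += dt * flux
    return u


def pad_pleura(arr: np.ndarray, lung_mask: np.ndarray | None) -> np.ndarray:
    """Replace pixels outside the lung mask by their nearest inside value.

    Removing the pleura during lung segmentation leaves a sharp intensity
    step along the mask boundary which would otherwise dominate the
    gradient and stall fronts there.  Nearest-inside filling (Euclidean
    distance transform) nulls that step while leaving lung content
    untouched.  Identity when no mask is given.
    """
    if lung_mask is None:
        return np.asarray(arr, dtype=float)
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if not lung_mask.any():
        raise ValueError("no lung region: all-false lung mask")
    arr = np.asarray(arr, dtype=float)
    _, (ir, ic) = ndimage.distance_transform_edt(~lung_mask, return_indices=True)
    return arr[ir, ic]


def gradient_magnitude(
    arr: np.ndarray,
    sigma: float = 1.0,
    mask: np.ndarray | None = None,
) -> GradientField:
    """Gaussian-smoothed gradient magnitude via central differences."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sm = ndimage.gaussian_filter(np.asarray(arr, dtype=float), sigma, mode="nearest")
    gy, gx = np.gradient(sm)
    G = np.hypot(gy, gx)
    domain = mask if mask is not None else np.ones_like(G, dtype=bool)
    total = float(G[domain].mean()) if domain.any() else 0.0
    return GradientField(G=G, total_grad_mean=total, mask=mask)


def speed_from_gradient(grad: GradientField, tau: float = -2.0) -> SpeedImage:
    """Exponential speed ``F = exp(tau * G)``, max-normalized to 1."""
    if tau >= 0:
        raise ValueError("tau must be negative")
    F = np.exp(tau * grad.G)
    F = F / F.max()
    return SpeedImage(F=F)


def _local_grad_mean(G: np.ndarray, domain: np.ndarray, r: int, c: int) -> float:
    """Mean gradient over the in-domain 3x3 patch centered on (r, c)."""
    h, w = G.shape
    rs, re = max(r - 1, 0), min(r + 2, h)
    cs, ce = max(c - 1, 0), min(c + 2, w)
    patch = G[rs:re, cs:ce]
    dom = domain[rs:re, cs:ce]
    if not dom.any():
        return float("inf")
    return float(patch[dom].mean())


def generate_seed_grid(
    grad: GradientField,
    mask: np.ndarray | None = None,
    seed_distance: int = 3,
    alpha: float = 1.0,
    beta: float = 2.0,
) -> SeedGrid:
    """Build the keep/shift/delete seed grid from an equidistant lattice.

    Lattice points (pitch ``seed_distance``, offset ``seed_distance//2``)
    outside the lung mask are ignored.  Each candidate's local gradient
    mean over its 3x3 neighbourhood is compared to the image-wide mean:

    * ``local > beta * total``  — deleted (not uniform enough);
    * ``alpha * total <= local <= beta * total`` — shifted to the
      neighbourhood pixel (diagonals included) with minimum local mean;
      the seed itself wins ties, then raster order;
    * ``local < alpha * total`` — kept in place.

    Duplicate positions after shifting are removed (first occurrence in
    raster order wins).
    """
    if seed_distance < 3:
        raise ValueError("seed_distance must be >= 3")
    if alpha > beta:
        raise ValueError("alpha must not exceed beta")
    G = grad.G
    h, w = G.shape
    domain = (
        np.asarray(mask, dtype=bool) if mask is not None else np.ones((h, w), bool)
    )
    total = grad.total_grad_mean

    seeds: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    off = seed_distance // 2
    for r in range(off, h, seed_distance):
        for c in range(off, w, seed_distance):
            if not domain[r, c]:
                continue
            local = _local_grad_mean(G, domain, r, c)
            if local > beta * total:
                continue  # rule 1: delete
            if local >= alpha * total:
                # rule 2: shift to the flattest neighbourhood pixel
                best = (local, (r, c))
                for nr in range(max(r - 1, 0), min(r + 2, h)):
                    for nc in range(max(c - 1, 0), min(c + 2, w)):
                        if (nr, nc) == (r, c) or not domain[nr, nc]:
                            continue
                        cand = _local_grad_mean(G, domain, nr, nc)
                        if cand < best[0]:
                            best = (cand, (nr, nc))
                pos = best[1]
            else:
                pos = (r, c)  # rule 3: keep
            if pos not in seen:
                seen.add(pos)
                seeds.append(pos)

    if not seeds:
        raise NoSeedsError("no uniform region for seeding")
    return SeedGrid(
        seeds=seeds,
        seed_distance=seed_distance,
        alpha=alpha,
        beta=beta,
        params={"total_grad_mean": total},
    )
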