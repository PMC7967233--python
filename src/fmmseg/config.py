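"""Segmentation parameters and their defaults.

Two groups of parameters exist.  The fixed group (``sigma``, ``tau``,
``alpha``, ``beta``, ``seed_distance``) controls speed-image and seed-grid
construction and rarely needs changing.  The tunable group
(``cluster_density``, ``mean_threshold``) trades segmentation detail
against merging stability and is the knob users actually turn.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class SegmentationParams:
    """All parameters of the region-based fast marching pipeline.

    Attributes
    ----------
    sigma : float
        Standard deviation (px) of the Gaussian applied before the
        gradient-magnitude computation.
    tau : float
        Exponent of the speed function ``F = exp(tau * |grad|)``; must be
        negative so speed decays at edges.
    alpha, beta : float
        Seed-grid thresholds relative to the image-wide mean gradient:
        seeds in neighbourhoods below ``alpha * total`` are kept, between
        ``alpha * total`` and ``beta * total`` shifted towards flatter
        ground, above ``beta * total`` deleted.
    seed_distance : int
        Pitch (px) of the initial seed lattice; 3 is the densest
        supported grid and the default.
    cluster_density : int
        Pitch (px) of the lattice used to pick initial k-means centroids;
        lower values give more, smaller clusters.
    mean_threshold : float
        Maximum mean-intensity difference (normalized units) for two
        adjacent clusters to be merged into the nodule mask.
    diffusion_kappa, diffusion_iters, diffusion_dt :
        Conductance scale, iteration count and time step of the
        edge-preserving anisotropic diffusion pre-filter.
    """

    sigma: float = 1.0
    tau: float = -2.0
    alpha: float = 1.0
    beta: float = 2.0
    seed_distance: int = 3
    cluster_density: int = 7
    mean_threshold: float = 0.15
    diffusion_kappa: float = 0.05
    diffusion_iters: int = 10
    diffusion_dt: float = 0.15

    def __post_init__(self) -> None:
        if self.tau >= 0:
            raise ValueError("tau must be negative (speed decays with gradient)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.alpha > self.beta:
            raise ValueError("alpha must not exceed beta")
        if self.seed_distance < 3:
            raise ValueError("seed_distance must be >= 3")
        if self.cluster_density < 3:
            raise ValueError("cluster_density must be >= 3")
        if not 0.0 < self.mean_threshold < 1.0:
            raise ValueError("mean_threshold must lie in (0, 1)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SegmentationParams":
        return cls(**json.loads(Path(path).read_text()))


DEFAULT_PARAMS = SegmentationParams()
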