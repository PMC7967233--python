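"""Synthetic phantom-nodule crops with known ground truth.

Emulates a lung-phantom study: spherical nodules of 5/10/20 mm scanned at
tube currents of 30/60/99/197 mA, augmented into four categories
(solid-round, solid-irregular, sub-solid, cavitary) and three
surroundings (isolated, juxtapleural, juxtavascular).  Images are
rendered directly in the normalized [0, 1] intensity scale of the
preprocessing stage; intensity levels mirror aerated lung (~0.15, i.e.
about −850 HU), soft tissue (~0.65, about −90 HU on the −1000..+400
normalization) and chest wall (~0.9).

Everything is deterministic for a fixed configuration: the same config
(including ``rng_seed``) reproduces the same image and ground truth
bit for bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import NoduleImage

CATEGORIES = ("solid-round", "solid-irregular", "sub-solid", "cavitary")
SUBCATEGORIES = ("isolated", "juxtapleural", "juxtavascular")
DIAMETERS_MM = (5.0, 10.0, 20.0)
TUBE_CURRENTS_MA = (30.0, 60.0, 99.0, 197.0)

#: Normalized intensity levels.
LUNG_LEVEL = 0.15
NODULE_LEVEL = 0.65
WALL_LEVEL = 0.9
#: Sub-solid nodule-to-background contrast.
SUBSOLID_CONTRAST = 0.15
#: Quantum-noise anchor: sigma at 197 mA; scales as 1/sqrt(tube current).
NOISE_SIGMA_REF = 0.05
NOISE_CURRENT_REF = 197.0
#: Gaussian blur (px) applied to the clean rendering to soften rims.
RIM_BLUR_SIGMA = 0.7


def noise_sigma(tube_current_mA: float) -> float:
    """Additive-noise standard deviation for a given tube current."""
    if tube_current_mA <= 0:
        raise ValueError("tube current must be positive")
    return NOISE_SIGMA_REF * np.sqrt(NOISE_CURRENT_REF / tube_current_mA)


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of one synthetic nodule case."""

    category: str = "solid-round"
    subcategory: str = "isolated"
    diameter_mm: float = 10.0
    tube_current_mA: float = 197.0
    rng_seed: int = 0
    spacing: float = 0.5
    ring_fraction: float = 0.35  # cavitary: ring thickness / outer radius
    vessel_width_px: int = 3

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.subcategory not in SUBCATEGORIES:
            raise ValueError(f"unknown subcategory {self.subcategory!r}")
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be positive")
        if not 0 < self.ring_fraction < 1:
            raise ValueError("ring_fraction must lie in (0, 1)")
        if not 2 <= self.vessel_width_px <= 4:
            raise ValueError("vessel width must be 2-4 px")


@dataclass
class SynthCase:
    """A generated crop, its binary ground truth and the config used."""

    image: NoduleImage
    ground_truth: np.ndarray
    config: SynthConfig
    shape_mask: np.ndarray = field(default=None, repr=False)  # pre-category solid shape


def _grid(cfg: SynthConfig):
    side = int(np.floor(2.0 * cfg.diameter_mm / cfg.spacing + 0.5))
    center = (side - 1) / 2.0
    rr, cc = np.mgrid[0:side, 0:side]
    return side, center, rr - center, cc - center


def _radius_px(cfg: SynthConfig) -> float:
    return cfg.diameter_mm / (2.0 * cfg.spacing)


def _render(
    cfg: SynthConfig,
    shape: np.ndarray,
    gt: np.ndarray,
    nodule_level: float,
    cavity: np.ndarray | None,
    texture_rng: np.random.Generator | None,
) -> SynthCase:
    """Compose the clean scene, soften rims, add noise, package the case."""
    side, center, dr, dc = _grid(cfg)
    r0 = _radius_px(cfg)

    wall = None
    vessel = None
    lung_mask = None
    if cfg.subcategory == "juxtapleural":
        # straight pleural wall tangent to the nodule on the left
        wall = (dc + center) <= (center - r0)
        lung_mask = ~wall
        gt = gt & lung_mask
        shape = shape & lung_mask
    elif cfg.subcategory == "juxtavascular":
        # vertical vessel tangent to the nodule on the right
        w = cfg.vessel_width_px
        start = int(np.floor(center + r0 - 0.5))
        vessel = ((dc + center) >= start) & ((dc + center) < start + w)
        gt = gt & ~vessel

    clean = np.full((side, side), LUNG_LEVEL)
    if wall is not None:
        clean[wall] = WALL_LEVEL
    if vessel is not None:
        clean[vessel] = NODULE_LEVEL
    clean[shape] = nodule_level
    if texture_rng is not None:
        # slow multiplicative texture inside the nodule (sub-solid cases)
        field_ = ndimage.gaussian_filter(
            texture_rng.standard_normal((side, side)), 2.0
        )
        field_ = field_ / (field_.std() + 1e-12)
        clean = np.where(shape, clean * (1.0 + 0.10 * field_), clean)
    if cavity is not None:
        clean[cavity] = LUNG_LEVEL

    clean = ndimage.gaussian_filter(clean, RIM_BLUR_SIGMA)
    rng = np.random.default_rng(cfg.rng_seed)
    noisy = clean + rng.normal(0.0, noise_sigma(cfg.tube_current_mA), clean.shape)
    noisy = np.clip(noisy, 0.0, 1.0)

    img = NoduleImage(
        intensity=noisy,
        spacing=cfg.spacing,
        lung_mask=lung_mask,
        provenance={"synthetic": True, "category": cfg.category,
                    "subcategory": cfg.subcategory},
    )
    return SynthCase(image=img, ground_truth=gt, config=cfg, shape_mask=shape)


def make_base_disk(cfg: SynthConfig) -> SynthCase:
    """Centered solid disk of the configured diameter over lung background."""
    _, _, dr, dc = _grid(cfg)
    r0 = _radius_px(cfg)
    shape = np.hypot(dr, dc) <= r0
    return _render(cfg, shape, shape.copy(), NODULE_LEVEL, None, None)


def _warp_profile(cfg: SynthConfig, max_tries: int = 20):
    """Random radial boundary perturbation r(theta) = r0 * (1 + s(theta)).

    ``s`` is a sum of 2-3 sine harmonics of order 3-8 with amplitudes
    below 0.3; draws leaving the radius factor under 0.3 anywhere are
    resampled (bounded retries).
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.rng_seed, 7)))
    theta = np.linspace(0, 2 * np.pi, 720)
    for _ in range(max_tries):
        n_harm = int(rng.integers(2, 4))
        ks = rng.choice(np.arange(3, 9), size=n_harm, replace=False)
        amps = rng.uniform(0.04, 0.12, size=n_harm) * rng.choice([-1, 1], n_harm)
        phis = rng.uniform(0, 2 * np.pi, size=n_harm)
        s = lambda th, ks=ks, amps=amps, phis=phis: sum(  # noqa: E731
            a * np.sin(k * th + p) for k, a, p in zip(ks, amps, phis)
        )
        if (1.0 + s(theta)).min() > 0.3:
            return s
    raise RuntimeError("could not draw a valid boundary perturbation")


def warp_irregular(
    case: SynthCase,
    cfg: SynthConfig | None = None,
    profile=None,
) -> SynthCase:
    """Replace the circular boundary by an irregular radial perturbation.

    The solid shape becomes ``r <= r0 * (1 + s(theta))``; image and
    ground truth are rebuilt from the same analytic boundary, so both are
    warped identically by construction, and rims are smudged by the usual
    rendering blur.  ``profile`` overrides the random perturbation with
    an explicit callable ``s(theta)`` (the zero profile reproduces the
    base disk exactly).
    """
    cfg = cfg or case.config
    _, _, dr, dc = _grid(cfg)
    r0 = _radius_px(cfg)
    s = profile if profile is not None else _warp_profile(cfg)
    theta = np.arctan2(dr, dc)
    shape = np.hypot(dr, dc) <= r0 * (1.0 + s(theta))
    return _render(cfg, shape, shape.copy(), NODULE_LEVEL, None, None)


def apply_category(case: SynthCase, cfg: SynthConfig | None = None) -> SynthCase:
    """Apply category-specific alterations to a base/warped solid shape.

    sub-solid: contrast lowered to ~0.15 with multiplicative texture;
    cavitary: concentric cavity at lung intensity, ground truth = ring;
    (surroundings — wall/vessel — are handled by the renderer from the
    subcategory).
    """
    cfg = cfg or case.config
    shape = case.shape_mask
    if cfg.category in ("solid-round", "solid-irregular"):
        return _render(cfg, shape, shape.copy(), NODULE_LEVEL, None, None)
    if cfg.category == "sub-solid":
        rng = np.random.default_rng(np.random.SeedSequence((cfg.rng_seed, 13)))
        return _render(
            cfg, shape, shape.copy(), LUNG_LEVEL + SUBSOLID_CONTRAST, None, rng
        )
    # cavitary
    _, _, dr, dc = _grid(cfg)
    r0 = _radius_px(cfg)
    thickness = cfg.ring_fraction * r0
    if thickness < 1.0:
        raise ValueError("cavity ring thinner than one pixel: invalid config")
    inner = np.hypot(dr, dc) <= (r0 - thickness)
    cavity = inner & shape
    if not (shape & ~cavity).any():
        raise ValueError("cavity swallows the whole nodule: invalid config")
    gt = shape & ~cavity
    return _render(cfg, shape, gt, NODULE_LEVEL, cavity, None)


def make_case(cfg: SynthConfig) -> SynthCase:
    """Generate one case: base disk → optional warp → category features."""
    base = make_base_disk(cfg)
    if cfg.category != "solid-round":
        base = warp_irregular(base, cfg)
    return apply_category(base, cfg)


def make_dataset(
    n_per_cell: int | dict = 1,
    categories=CATEGORIES,
    subcategories=SUBCATEGORIES,
    diameters=DIAMETERS_MM,
    tube_currents=TUBE_CURRENTS_MA,
    seed: int = 0,
) -> tuple[list[SynthCase], pd.DataFrame]:
    """Deterministic cartesian sweep over the requested cells.

    ``n_per_cell`` is either an integer (cases per (category,
    subcategory) cell) or a mapping ``(category, subcategory) -> count``,
    which lets study-like composition tables be reproduced.  Within a
    cell, diameters and tube currents are cycled through in order.
    Returns the cases and a manifest DataFrame.
    """
    cells = list(itertools.product(categories, subcategories))
    counts = {
        cell: (n_per_cell[cell] if isinstance(n_per_cell, dict) else int(n_per_cell))
        for cell in cells
    }
    if any(v < 0 for v in counts.values()):
        raise ValueError("cell counts must be non-negative")

    total = sum(counts.values())
    ss = np.random.SeedSequence(seed)
    case_seeds = [int(s) % (2**31) for s in ss.generate_state(max(total, 1))]

    combos = list(itertools.product(diameters, tube_currents))
    cases: list[SynthCase] = []
    rows = []
    idx = 0
    for cat, sub in cells:
        for i in range(counts[(cat, sub)]):
            diam, curr = combos[i % len(combos)]
            cfg = SynthConfig(
                category=cat,
                subcategory=sub,
                diameter_mm=float(diam),
                tube_current_mA=float(curr),
                rng_seed=case_seeds[idx],
            )
            cases.append(make_case(cfg))
            rows.append(
                {
                    "case_id": idx,
                    "category": cat,
                    "subcategory": sub,
                    "diameter_mm": float(diam),
                    "tube_current_mA": float(curr),
                    "rng_seed": cfg.rng_seed,
                }
            )
            idx += 1
    return cases, pd.DataFrame(rows)


def replace_config(cfg: SynthConfig, **kw) -> SynthConfig:
    """Functional update helper (frozen dataclass)."""
    return replace(cfg, **kw)
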