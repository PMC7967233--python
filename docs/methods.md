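# Methods

`fmmseg` segments lung nodules in 2D CT crops by a region-based fast
marching method: it over-partitions the crop into small regions by
propagating fronts from a dense seed grid over a gradient-derived speed
image, groups the regions into clusters with deterministically
initialized k-means, and grows the final mask cluster-by-cluster under a
mean-intensity merging criterion. This note records the model, the
parameters that matter, the numerical choices, what the phantom
simulator does and does not emulate, and the known limitations.

## The model

The core solver computes the first-arrival time `T(x, y)` of a front
moving with positive speed `F(x, y)`, i.e. the viscosity solution of the
Eikonal equation `|∇T| · F = 1` with `T = 0` on the seed set. The speed
is an inverse function of the image gradient,

    F = exp(τ · |∇(G_σ * I)|) / max(·),      τ = −2, σ = 1,

so fronts run freely through homogeneous tissue (`F ≈ 1`) and stall at
intensity edges (`F ≈ 0`). With one front per seed, each pixel is
assigned to the seed whose front arrives first, producing a complete
partition of the crop ("stained glass"). Region boundaries concentrate
on image edges because fronts from both sides stall there.

The partition is deliberately finer than the anatomy. Regions are
therefore grouped into clusters by k-means on **seed coordinates** —
seeds survive the gradient filter only in uniform areas, so seeds of the
same tissue pack together spatially — and the nodule mask is grown over
the cluster adjacency graph: starting from a cluster chosen to lie
inside the nodule, a neighbour `j` of an accepted cluster `i` is
accepted iff `|mean_i − mean_j| < mean_threshold`, pairwise, not against
a running blob mean. Intensity is deliberately *not* a clustering
feature; it is reserved for the merging criterion.

The start cluster maximizes `mean_intensity / (dist(centroid, image
center) + ε)` with `ε = 1 px`, combining the two priors available in a
nodule-centered crop: nodules are usually bright and usually central.

## Parameters

| name | default | units | role |
| --- | --- | --- | --- |
| `sigma` | 1.0 | px | Gaussian smoothing before the gradient |
| `tau` | −2.0 | — | speed exponent; more negative → harder edge stopping |
| `alpha`, `beta` | 1.0, 2.0 | — | seed keep/shift/delete thresholds relative to the mean gradient |
| `seed_distance` | 3 | px | seed lattice pitch (3 = densest supported) |
| `cluster_density` | 7 | px | centroid lattice pitch; lower → more, smaller clusters |
| `mean_threshold` | 0.15 | intensity | maximum cluster mean difference for merging |
| `diffusion_kappa` | 0.05 | intensity | Perona–Malik conductance scale |
| `diffusion_iters`, `diffusion_dt` | 10, 0.15 | — | diffusion iterations / step |

The first five are fixed operating points; `cluster_density` and
`mean_threshold` are the tunables a user would adjust. All intensities
are on the normalized scale (−1000 HU → 0, +400 HU → 1), so
`mean_threshold = 0.15` corresponds to a 210 HU contrast.

Seed filtering compares the mean gradient over a seed's 3×3
neighbourhood (`local`) with the image-wide mean over the lung domain
(`total`): `local > β·total` deletes the seed, `α·total ≤ local ≤
β·total` shifts it to the flattest of its nine neighbourhood pixels
(diagonals included; the seed itself wins exact ties, then raster
order), `local < α·total` keeps it. The three rules are implemented as a
partition of the line, which for the default `α = 1` coincides with
every reading of the rule set. On a perfectly flat image (`total = 0`)
the shift band is the degenerate interval `0 ≤ 0 ≤ 0`; the self-wins
tie-break then returns the full lattice, which is the intended
behaviour.

## Numerical choices

* **Upwind update.** First-order Godunov on the 4-neighbour stencil:
  with `a = min(T_W, T_E)`, `b = min(T_N, T_S)` and `h/F` the local
  cost, the 1D update `min(a,b) + h/F` applies when `|a − b| ≥ h/F`,
  otherwise the larger root of `(T−a)² + (T−b)² = (h/F)²`. Grid step
  `h = 1` pixel; crops are isotropic so spacing-aware marching is not
  needed.
* **Heap policy.** Lazy deletion: stale entries are pushed freely and
  skipped on pop, preserving the `N log N` bound without decrease-key.
* **Point-source initialization.** Seeds freeze at `T = 0`; their
  4-neighbours enter the band at exactly `1/F`. Because a first-order
  scheme loses accuracy at the non-smooth arrival surface of a point
  source, the rest of the Chebyshev-radius-2 box around each seed is
  additionally initialized with the straight-line estimate
  `dist · (S_seed + S_pixel)/2` (trapezoid slowness). This bounds the
  uniform-speed error at ≤ 1 grid step over a 64×64 crop; without it the
  error reaches 1.17. Seeds sit in gradient-filtered flat areas, so the
  2-px straight line does not skip edge barriers in practice. Narrow-band
  pixels adjacent to two frozen seeds are settled with the upwind
  quadratic at initialization; otherwise the quadratic would undercut the
  1D estimate mid-march and break the monotone pop order.
* **Determinism.** Exact heap ties resolve by raster order `(T, row,
  col)`, label ties by the lowest-raster known neighbour, k-means is
  initialized at the filtered centroid lattice (never randomly), and BFS
  merging iterates sorted ids. Two runs with identical inputs produce
  byte-identical masks, and the partition is invariant to seed insertion
  order except where exact arrival ties occur.
* **Degenerate inputs.** All-false lung mask → error; no surviving seed
  → error ("no uniform region for seeding"); pixels isolated by the mask
  are labelled with a sentinel and a warning; an empty final mask warns
  and returns the start cluster's pixels only before domain restriction.
* **Pleura padding.** Pixels outside the lung mask take the value of
  their nearest inside pixel (Euclidean distance transform with index
  return). This exactly nulls the mask-boundary step so juxtapleural
  fronts are not stalled by the lung segmentation itself.
* **Diameters.** Long axis = maximal center-to-center distance between
  border pixels (border = mask pixels with a 4-neighbour outside),
  computed on the largest connected component; short axis = maximal
  extent perpendicular to the long axis over unit-width slabs along it.
  No +1 px pixel-extent correction is applied, which shifts diameters by
  about half a pixel versus edge-to-edge conventions; reported values
  are rounded to whole millimetres (round-half-up), unrounded values are
  kept internally. Sample (n−1) standard deviations in aggregates.

## The phantom simulator

`fmmseg.phantom` emulates an altered-phantom study design: spherical
nodules of 5/10/20 mm at 0.5 mm/px, four noise levels indexed by tube
current (30/60/99/197 mA), four categories (solid-round,
solid-irregular, sub-solid, cavitary) and three surroundings (isolated,
juxtapleural, juxtavascular), with ground truth known by construction.
Specifics:

* Intensity levels 0.15 (aerated lung), 0.65 (soft-tissue nodule), 0.9
  (chest wall) on the normalized scale, matching roughly −850, −90 and
  +260 HU.
* Noise is additive Gaussian with `σ = 0.05 · sqrt(197 / mA)` — the
  standard quantum-noise scaling anchored at the highest-quality scan.
* Irregular shapes are analytic radial perturbations `r(θ) = r₀(1 + Σ aₖ
  sin(kθ + φₖ))`, harmonics k ∈ [3, 8], 2–3 per shape, |aₖ| ≤ 0.12;
  image and ground truth derive from the same boundary, and all rims are
  softened with a σ = 0.7 px blur.
* Sub-solid: contrast lowered to ≈ 0.15 with a slow multiplicative
  texture; cavitary: concentric cavity at lung intensity, ring thickness
  0.35·r₀, truth = ring only; juxtapleural: straight bright wall tangent
  to the nodule with the lung mask excluding it; juxtavascular: 3 px
  bright vessel tangent to the nodule, excluded from the truth.

What it does **not** emulate: CT physics (no sinogram or reconstruction,
so no streak artifacts or correlated noise), volume partial-volume
effects, textured parenchyma (vessel trees, fissures), or annotation
error (crops are perfectly centered). Passing tests on this simulator
therefore demonstrate the algorithmic contracts and the behaviour of the
pipeline under controlled contrast/noise/geometry, not clinical
performance on patient data.

## Benchmark composition and problem sizes

The benchmark used by `scripts/acceptance.py` follows the study-style
composition (36 solid-round, 36 solid-irregular, 18 sub-solid, 18
cavitary, each split 4:1:1 across isolated/juxtapleural/juxtavascular),
sweeping diameters and tube currents cyclically within each cell — 108
cases, each a 20–80 px crop. Solver-validation checks run on 32×32
random smooth speed fields against an 8-connected Dijkstra oracle and on
a 64×64 uniform-speed grid against the Euclidean distance map.

## Known limitations

* **Sub-solid nodules with contrast at the merge threshold.** The
  simulator's sub-solid contrast (≈ 0.15) coincides with the default
  `mean_threshold`, so nodule/background cluster differences sit exactly
  at the accept/reject boundary and rim clusters with intermediate means
  can bridge them; the typical outcome is flooding (over-segmentation)
  or, with slightly different noise draws, under-segmentation. This is
  the documented hard regime of pairwise mean merging.
* **Concentric cavitary nodules.** The start-cluster ratio
  `mean/(dist + ε)` lets a dark cavity cluster sitting exactly at the
  crop center outrank the bright ring (0.15/2 > 0.6/17), inverting the
  segmentation. With perfectly concentric cavities in perfectly centered
  crops this geometry occurs systematically, so cavitary scores here are
  substantially below what off-center or thick-ring cases yield; the
  criterion as printed trades this failure mode for robustness on
  bright-obstruction cases.
* The pipeline is strictly 2D (single-slice crops) and performs no
  automatic parameter optimization; `cluster_density` and
  `mean_threshold` are manual tunables.
* Lung segmentation matches the usual threshold + components + per-lung
  convex hull contract but is not a reimplementation of any specific
  published kernel; the hull step intentionally over-includes along
  concave mediastinal borders.
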