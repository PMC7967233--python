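# fmmseg — region-based fast marching lung-nodule segmentation

`fmmseg` segments lung nodules in 2D CT crops for CADx-style
measurement. Nodules are hard to delineate because their attenuation
often matches the pleura, vessels or surrounding parenchyma; plain
region growing is brittle because its merging criterion is applied to
tiny regions. This package implements a region-based variant of the fast
marching method that addresses both problems:

1. **Speed image & seed grid** — the crop is denoised with Perona–Malik
   anisotropic diffusion, pixels outside the lung mask are filled with
   their nearest lung value (so the pleural boundary contributes no
   gradient), and the front speed is `F = exp(−2·|∇(G₁ * I)|)`,
   max-normalized. Seeds start on a 3 px lattice and are deleted,
   diagonally shifted, or kept by comparing their local mean gradient
   with the image-wide mean (thresholds α = 1, β = 2).
2. **Multi-label fast marching** — one front per seed solves
   `|∇T|·F = 1` with a first-order upwind scheme and a min-heap,
   assigning every pixel to the seed that reaches it first: a complete
   "stained-glass" partition whose boundaries follow image edges.
3. **Cluster merging** — regions are grouped by k-means on seed
   coordinates (centroids from the same lattice filter at pitch 7, so
   clustering is deterministic), a start cluster is picked by the ratio
   `mean intensity / (distance to crop center + 1)`, and neighbouring
   clusters are merged while their pairwise mean difference stays below
   0.15.

A phantom-nodule simulator (solid-round / solid-irregular / sub-solid /
cavitary nodules; isolated / juxtapleural / juxtavascular surroundings;
5/10/20 mm; tube-current-indexed noise) provides ground truth for the
objective evaluator: Dice overlap and long/short-axis diameter relative
errors measured by the radiological convention (maximal border distance
and maximal perpendicular chord, to the nearest millimetre).

## Worked example

```python
import numpy as np
from fmmseg import SynthConfig, make_case, segment, dice, evaluate_case

case = make_case(SynthConfig(category="solid-round", diameter_mm=10.0,
                             tube_current_mA=197.0, rng_seed=12345))
mask = segment(case.image)            # default parameters
row = evaluate_case(mask.mask, case)
print(f"dice        {row['dice']:.3f}")
print(f"long axis   {row['long_axis_seg_mm']} mm (truth {row['long_axis_gt_mm']} mm)")
print(f"e_long      {row['e_long_pct']:.1f} %")
```

prints

```
dice        0.982
long axis   10 mm (truth 10 mm)
e_long      0.0 %
```

i.e. the simulated 10 mm solid nodule is recovered with 98% overlap and
its long-axis diameter measured exactly, which is what the method is
for: reproducible size measurements on already-detected nodules.

The same pipeline is scriptable from the shell:

```bash
fmmseg synth --out data --n-per-cell 1 --seed 3          # phantom cases + truth
fmmseg segment --in data/case_0000.npz --out mask_0000   # one crop -> mask
fmmseg run-bench --out bench --n-per-cell 2 --seed 0     # synth + segment + eval
fmmseg preprocess --dicom-dir scan/ --centroid 41,256,310 \
    --diameter-mm 8 --out crop.npz                       # real CT input
```

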