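"""Objective segmentation evaluation: Dice and diameter relative errors.

Diameters follow the radiological measurement convention: the long-axis
diameter is the maximal distance between two border points of the
nodule, the short-axis diameter the maximal chord through the nodule
perpendicular to the long axis, both expressed to the nearest whole
millimetre for reporting.  Distances are measured center-to-center
between pixels, with no pixel-extent correction (a convention that
shifts diameters by about half a pixel relative to edge-to-edge
measurement).  Measurement is performed on the largest connected
component of the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import pdist, squareform

from .phantom import SynthCase


def dice(A: np.ndarray, B: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A| + |B|)``.

    Two empty masks are defined to agree perfectly (1.0).
    """
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise ValueError("mask shapes differ")
    denom = int(A.sum()) + int(B.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((A & B).sum()) / denom


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def _border_pixels(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with a 4-neighbour outside the mask (or on the edge)."""
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return mask & ~interior


def measure_diameters(mask: np.ndarray, spacing: float) -> tuple[float, float]:
    """Long- and short-axis diameters (mm, unrounded) of a binary mask.

    Long axis: maximal pairwise center-to-center distance between border
    pixels.  Short axis: the coordinates of all mask pixels are rotated
    into the long-axis frame, binned into unit-width slabs along the long
    axis, and the maximal perpendicular extent over the slabs is taken.
    A single-pixel-wide mask has zero short axis (sub-pixel widths are
    not resolved).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("nothing to measure: empty mask")
    comp = _largest_component(mask)
    border = np.argwhere(_border_pixels(comp)).astype(float)
    if len(border) == 1:
        return 0.0, 0.0

    D = squareform(pdist(border))
    i, j = np.unravel_index(np.argmax(D), D.shape)
    long_px = float(D[i, j])
    direction = border[j] - border[i]
    u = direction / np.linalg.norm(direction)
    v = np.array([-u[1], u[0]])

    pts = np.argwhere(comp).astype(float)
    pu = pts @ u
    pv = pts @ v
    bins = np.floor(pu - pu.min() + 0.5).astype(int)
    short_px = 0.0
    for b in np.unique(bins):
        sel = bins == b
        ext = float(pv[sel].max() - pv[sel].min())
        short_px = max(short_px, ext)
    short_px = min(short_px, long_px)  # a chord cannot exceed the diameter
    return long_px * spacing, short_px * spacing


def round_mm(x: float) -> int:
    """Round a diameter to the nearest whole millimetre (half-up)."""
    return int(np.floor(x + 0.5))


def relative_error(ms: float, mgt: float) -> float:
    """Relative error percentage ``|ms - mgt| / mgt * 100``."""
    if mgt <= 0:
        raise ValueError("ground-truth measurement must be positive")
    return abs(ms - mgt) / mgt * 100.0


@dataclass
class EvalReport:
    """Per-case metrics and per-category aggregates."""

    per_case: pd.DataFrame
    per_category: pd.DataFrame

    def to_csv(self, path) -> None:
        self.per_case.to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        flat = self.per_category.copy()
        flat.columns = ["_".join(c) for c in flat.columns]
        Path(path).write_text(
            json.dumps(
                {
                    "per_case": self.per_case.to_dict(orient="records"),
                    "per_category": flat.reset_index().to_dict(orient="records"),
                },
                indent=2,
            )
        )


def evaluate_case(pred: np.ndarray, case: SynthCase) -> dict:
    """Dice plus diameter errors of one prediction against its truth."""
    gt = case.ground_truth
    spacing = case.image.spacing
    d = dice(pred, gt)
    gl, gs = measure_diameters(gt, spacing)
    if pred.any():
        sl, ss = measure_diameters(pred, spacing)
    else:
        sl, ss = 0.0, 0.0
    gl_r, gs_r = round_mm(gl), round_mm(gs)
    sl_r, ss_r = round_mm(sl), round_mm(ss)
    return {
        "category": case.config.category,
        "subcategory": case.config.subcategory,
        "diameter_mm": case.config.diameter_mm,
        "tube_current_mA": case.config.tube_current_mA,
        "dice": d,
        "long_axis_seg_mm": sl_r,
        "short_axis_seg_mm": ss_r,
        "long_axis_gt_mm": gl_r,
        "short_axis_gt_mm": gs_r,
        "e_long_pct": relative_error(sl_r, gl_r) if gl_r > 0 else np.nan,
        "e_short_pct": relative_error(ss_r, gs_r) if gs_r > 0 else np.nan,
    }


def evaluate_dataset(pairs) -> EvalReport:
    """Evaluate (prediction, case) pairs and aggregate per category.

    Aggregates are the mean and sample (n−1) standard deviation of Dice
    and both diameter errors; single-case categories report sd 0 with an
    ``n=1`` flag column.
    """
    rows = [evaluate_case(pred, case) for pred, case in pairs]
    per_case = pd.DataFrame(rows)
    metrics = ["dice", "e_long_pct", "e_short_pct"]
    agg = per_case.groupby("category")[metrics].agg(["mean", "std", "count"])
    agg = agg.rename(columns={"count": "n"})
    for m in metrics:
        agg[(m, "std")] = agg[(m, "std")].fillna(0.0)
    return EvalReport(per_case=per_case, per_category=agg)
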