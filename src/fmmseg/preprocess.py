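"""CT preprocessing: resampling, lung segmentation, normalization, cropping.

Turns a raw CT volume plus a nodule annotation (centroid + approximate
diameter) into a square, normalized, nodule-centered 2D crop with an
optional lung mask — the input expected by the segmentation pipeline.

Conventions used throughout: 0-based ``(row, col)`` pixel coordinates,
pixel centers at integer positions, half-open crop windows, and
round-half-up when a physical length is converted to a pixel count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pydicom
from scipy import ndimage
from skimage.morphology import closing, convex_hull_image, disk

HU_MIN = -1000.0
HU_MAX = 400.0
#: Air/parenchyma threshold used by the lung segmentation (HU).
LUNG_AIR_THRESHOLD_HU = -320.0


class EmptyMaskWarning(UserWarning):
    """Raised when lung segmentation finds no lung tissue."""


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units with (z, y, x) voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive on all axes")


@dataclass
class NoduleAnnotation:
    """Nodule centroid and approximate diameter.

    ``centroid`` is (z, y, x); ``in_mm=True`` means physical millimetres
    (relative to the volume origin), otherwise voxel indices.
    """

    centroid: tuple[float, float, float]
    diameter_mm: float
    in_mm: bool = False

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be positive")

    def voxel_centroid(self, vol: CTVolume) -> tuple[float, float, float]:
        if not self.in_mm:
            c = self.centroid
        else:
            c = tuple(
                (p - o) / s for p, o, s in zip(self.centroid, vol.origin, vol.spacing)
            )
        for i, (p, n) in enumerate(zip(c, vol.voxels.shape)):
            if not 0 <= p <= n - 1:
                raise ValueError(f"centroid outside volume bounds on axis {i}")
        return c  # type: ignore[return-value]


@dataclass
class NoduleImage:
    """Normalized, square, nodule-centered 2D crop.

    ``intensity`` holds values in [0, 1] (−1000 HU → 0, +400 HU → 1);
    ``spacing`` is the isotropic in-plane pixel size in mm; ``lung_mask``
    (optional, True = lung interior) restricts the segmentation domain.
    """

    intensity: np.ndarray
    spacing: float
    lung_mask: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2D")
        h, w = self.intensity.shape
        if h != w:
            raise ValueError("crop must be square")
        if self.intensity.min() < -1e-9 or self.intensity.max() > 1 + 1e-9:
            raise ValueError("intensity must lie in [0, 1]")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.lung_mask is not None:
            self.lung_mask = np.asarray(self.lung_mask, dtype=bool)
            if self.lung_mask.shape != self.intensity.shape:
                raise ValueError("lung_mask shape must match intensity")


# ---------------------------------------------------------------------------
# DICOM / array I/O


def read_dicom_series(paths_or_dir) -> CTVolume:
    """Read a DICOM CT series into a :class:`CTVolume` (HU voxels).

    Accepts a directory or an explicit list of .dcm files.  Slices are
    sorted by their z position; RescaleSlope/Intercept are applied.
    """
    from pathlib import Path

    p = Path(paths_or_dir) if isinstance(paths_or_dir, (str, bytes)) or hasattr(
        paths_or_dir, "__fspath__"
    ) else None
    if p is not None and p.is_dir():
        files = sorted(p.glob("*.dcm")) or sorted(p.iterdir())
    else:
        files = list(paths_or_dir)  # type: ignore[arg-type]
    datasets = [pydicom.dcmread(str(f)) for f in files]
    if not datasets:
        raise ValueError("no DICOM files found")

    def zpos(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=zpos)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    voxels = np.stack(slices, axis=0)

    ds0 = datasets[0]
    py, px = (float(v) for v in getattr(ds0, "PixelSpacing", [1.0, 1.0]))
    if len(datasets) > 1:
        dz = abs(zpos(datasets[1]) - zpos(datasets[0]))
        if dz == 0:
            dz = float(getattr(ds0, "SliceThickness", 1.0))
    else:
        dz = float(getattr(ds0, "SliceThickness", 1.0))
    origin = tuple(
        float(v)
        for v in (
            getattr(ds0, "ImagePositionPatient", [0.0, 0.0, 0.0])[2],
            getattr(ds0, "ImagePositionPatient", [0.0, 0.0, 0.0])[1],
            getattr(ds0, "ImagePositionPatient", [0.0, 0.0, 0.0])[0],
        )
    )
    return CTVolume(voxels=voxels, spacing=(dz, py, px), origin=origin)


def load_volume(path) -> CTVolume:
    """Load a CTVolume from .npz (keys voxels/spacing[/origin]) or .npy."""
    from pathlib import Path

    path = Path(path)
    if path.suffix == ".npz":
        d = np.load(path)
        origin = tuple(d["origin"]) if "origin" in d else (0.0, 0.0, 0.0)
        return CTVolume(d["voxels"], tuple(d["spacing"]), origin)
    return CTVolume(np.load(path), (1.0, 1.0, 1.0))


def save_crop(img: NoduleImage, path) -> None:
    """Write a crop as .npz with a JSON-serializable sidecar inside."""
    import json

    np.savez(
        path,
        intensity=img.intensity,
        spacing=img.spacing,
        lung_mask=(
            img.lung_mask if img.lung_mask is not None else np.zeros((0, 0), bool)
        ),
        provenance=np.array(json.dumps(img.provenance)),
    )


def load_crop(path) -> NoduleImage:
    import json

    d = np.load(path, allow_pickle=False)
    mask = d["lung_mask"]
    return NoduleImage(
        intensity=d["intensity"],
        spacing=float(d["spacing"]),
        lung_mask=None if mask.size == 0 else mask,
        provenance=json.loads(str(d["provenance"])) if "provenance" in d else {},
    )


# ---------------------------------------------------------------------------
# Operations


def resample_volume(vol: CTVolume, target_spacing: float = 0.5) -> CTVolume:
    """Resample the in-plane axes to an isotropic target spacing.

    Third-order spline interpolation; the output pixel at index ``j``
    samples the input at physical position ``j * target_spacing``, so
    when the ratio of spacings is an integer the original grid points are
    reproduced exactly.  Output dimensions are ``round(n * old/target)``
    (round-half-up).  The z axis is left untouched.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    nz, ny, nx = vol.voxels.shape
    sy, sx = vol.spacing[1], vol.spacing[2]
    new_ny = max(1, _round_half_up(ny * sy / target_spacing))
    new_nx = max(1, _round_half_up(nx * sx / target_spacing))

    yy = np.arange(new_ny) * target_spacing / sy
    xx = np.arange(new_nx) * target_spacing / sx
    gy, gx = np.meshgrid(yy, xx, indexing="ij")
    out = np.empty((nz, new_ny, new_nx))
    for k in range(nz):
        out[k] = ndimage.map_coordinates(
            vol.voxels[k], [gy, gx], order=3, mode="nearest"
        )
    return CTVolume(out, (vol.spacing[0], target_spacing, target_spacing), vol.origin)


def segment_lungs(slice2d: np.ndarray) -> np.ndarray:
    """Segment the lung interior of an axial HU slice.

    Thresholding at −320 HU, connected-component selection (interior
    components only, at most the two largest) and a per-lung convex hull
    so that wall-attached (juxtapleural) nodules remain inside the mask.
    Returns an all-false mask with a warning when no lung is found.
    """
    slice2d = np.asarray(slice2d, dtype=float)
    air = slice2d < LUNG_AIR_THRESHOLD_HU
    if not air.any():
        warnings.warn("no sub-threshold region: empty lung mask", EmptyMaskWarning)
        return np.zeros_like(air)

    labels, n = ndimage.label(air)
    if n == 0:
        warnings.warn("no connected air region: empty lung mask", EmptyMaskWarning)
        return np.zeros_like(air)

    # Components touching the image border are outside-body air.
    border_labels = set(labels[0, :]) | set(labels[-1, :]) | set(labels[:, 0]) | set(
        labels[:, -1]
    )
    border_labels.discard(0)
    sizes = ndimage.sum_labels(air, labels, index=np.arange(1, n + 1))
    interior = [
        (sizes[i - 1], i) for i in range(1, n + 1) if i not in border_labels
    ]
    if not interior:
        warnings.warn("only border-touching air found: empty lung mask", EmptyMaskWarning)
        return np.zeros_like(air)
    interior.sort(reverse=True)
    keep = [lab for _, lab in interior[:2]]

    selem = disk(5)
    out = np.zeros_like(air)
    for lab in keep:
        comp = labels == lab
        comp = closing(comp, selem)
        if comp.any():
            out |= convex_hull_image(comp)
    return out


def normalize_hu(slice2d: np.ndarray) -> np.ndarray:
    """Linearly map [−1000, +400] HU to [0, 1], clipping outside values."""
    slice2d = np.asarray(slice2d, dtype=float)
    return np.clip((slice2d - HU_MIN) / (HU_MAX - HU_MIN), 0.0, 1.0)


def crop_nodule(
    slice2d: np.ndarray,
    mask: np.ndarray | None,
    ann_row: float,
    ann_col: float,
    diameter_mm: float,
    spacing: float,
) -> NoduleImage:
    """Extract a square crop of side ``2 * diameter`` centered on the nodule.

    ``slice2d`` must already be normalized to [0, 1].  The side length is
    ``round(2 * diameter / spacing)`` px (round-half-up) and the pixel at
    index ``side // 2`` is the rounded annotated centroid.  Windows that
    extend past the slice are zero-padded (False-padded for the mask) and
    the padding is recorded in the provenance.
    """
    slice2d = np.asarray(slice2d, dtype=float)
    h, w = slice2d.shape
    if not (0 <= ann_row <= h - 1 and 0 <= ann_col <= w - 1):
        raise ValueError("centroid outside slice")
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")

    side = max(1, _round_half_up(2.0 * diameter_mm / spacing))
    r0 = _round_half_up(ann_row) - side // 2
    c0 = _round_half_up(ann_col) - side // 2

    out = np.zeros((side, side), dtype=float)
    out_mask = np.zeros((side, side), dtype=bool) if mask is not None else None
    rs, re = max(r0, 0), min(r0 + side, h)
    cs, ce = max(c0, 0), min(c0 + side, w)
    out[rs - r0 : re - r0, cs - c0 : ce - c0] = slice2d[rs:re, cs:ce]
    if out_mask is not None:
        out_mask[rs - r0 : re - r0, cs - c0 : ce - c0] = mask[rs:re, cs:ce]

    padded = (rs != r0) or (cs != c0) or (re != r0 + side) or (ce != c0 + side)
    prov = {
        "crop_window": [int(r0), int(c0), int(side)],
        "zero_padded": bool(padded),
    }
    return NoduleImage(out, spacing, lung_mask=out_mask, provenance=prov)


def prepare_nodule_image(
    vol: CTVolume,
    ann: NoduleAnnotation,
    target_spacing: float = 0.5,
    with_lung_mask: bool = True,
) -> NoduleImage:
    """Full preprocessing chain: resample → lung mask → normalize → crop."""
    cz, cy, cx = ann.voxel_centroid(vol)
    res = resample_volume(vol, target_spacing)
    scale_y = vol.spacing[1] / target_spacing
    scale_x = vol.spacing[2] / target_spacing
    k = int(round(cz))
    slice_hu = res.voxels[k]
    mask = segment_lungs(slice_hu) if with_lung_mask else None
    norm = normalize_hu(slice_hu)
    return crop_nodule(
        norm, mask, cy * scale_y, cx * scale_x, ann.diameter_mm, target_spacing
    )
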