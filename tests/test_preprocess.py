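import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmmseg.preprocess import (
    CTVolume,
    EmptyMaskWarning,
    NoduleAnnotation,
    crop_nodule,
    normalize_hu,
    read_dicom_series,
    resample_volume,
    segment_lungs,
)

from _oracles import point_in_hull


# ---------------------------------------------------------------- types


def test_volume_validation_rejects_bad_spacing_and_empty_arrays():
    with pytest.raises(ValueError):
        CTVolume(np.zeros((2, 4, 4)), spacing=(1.0, 0.0, 1.0))
    with pytest.raises(ValueError):
        CTVolume(np.zeros((2, 4)), spacing=(1.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        NoduleAnnotation((1, 1, 1), diameter_mm=-3)


def test_annotation_centroid_bounds_checked():
    vol = CTVolume(np.zeros((3, 10, 10)), spacing=(1.0, 1.0, 1.0))
    ann = NoduleAnnotation((0, 20, 5), diameter_mm=5)
    with pytest.raises(ValueError, match="outside volume"):
        ann.voxel_centroid(vol)
    ann_mm = NoduleAnnotation((0.0, 4.0, 4.0), diameter_mm=5, in_mm=True)
    assert ann_mm.voxel_centroid(vol) == (0.0, 4.0, 4.0)


# ---------------------------------------------------------------- resample


def test_resample_halving_spacing_doubles_inplane_dimensions():
    vol = CTVolume(np.zeros((1, 100, 100)), spacing=(1.0, 1.0, 1.0))
    out = resample_volume(vol, 0.5)
    assert out.voxels.shape == (1, 200, 200)
    assert out.spacing == (1.0, 0.5, 0.5)


def test_resample_constant_volume_stays_constant():
    vol = CTVolume(np.full((2, 30, 30), -650.0), spacing=(1.0, 1.0, 1.0))
    out = resample_volume(vol, 0.7)
    assert np.allclose(out.voxels, -650.0)


def test_resample_linear_ramp_reproduced_at_original_grid_points():
    # cubic splines reproduce polynomials up to degree 3; with a 2x
    # upsampling every second output pixel sits on an input grid point
    y = np.arange(40, dtype=float)
    ramp = np.tile(3.0 * y, (40, 1))
    vol = CTVolume(ramp[None], spacing=(1.0, 1.0, 1.0))
    out = resample_volume(vol, 0.5)
    assert np.allclose(out.voxels[0][::2, ::2], ramp, atol=1e-6)


def test_resample_rejects_nonpositive_spacing():
    vol = CTVolume(np.zeros((1, 4, 4)), spacing=(1.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        resample_volume(vol, -1.0)


# ---------------------------------------------------------------- lungs


def _two_lung_slice(bump=False):
    """+40 HU body with two -1000 HU lung disks; optional wall bump."""
    sl = np.full((80, 80), 40.0)
    yy, xx = np.mgrid[0:80, 0:80]
    left = np.hypot(yy - 40, xx - 22) < 14
    right = np.hypot(yy - 40, xx - 58) < 14
    sl[left | right] = -1000.0
    if bump:
        # soft-tissue bump attached to the left lung's wall
        bump_mask = np.hypot(yy - 40, xx - 9.5) < 4
        sl[bump_mask] = 40.0
    return sl, left, right


def test_lung_mask_recovers_the_two_disks():
    sl, left, right = _two_lung_slice()
    mask = segment_lungs(sl)
    truth = left | right
    # hulls of disks are the disks themselves (up to pixelation)
    agree = (mask & truth).sum() / max(truth.sum(), 1)
    assert agree > 0.97
    assert (mask & ~truth).sum() < 0.1 * truth.sum()


def test_juxtapleural_bump_recovered_by_convex_hull():
    sl, left, right = _two_lung_slice(bump=True)
    mask = segment_lungs(sl)
    air_component = (sl < -320) & (np.hypot(*(np.mgrid[0:80, 0:80] - np.array([[[40]], [[22]]]))) < 20)
    pts = np.argwhere(air_component)
    yy, xx = np.mgrid[0:80, 0:80]
    bump_interior = np.hypot(yy - 40, xx - 9.5) < 2.5
    queries = np.argwhere(bump_interior)
    inside_hull = point_in_hull(pts, queries)
    # every bump pixel the brute-force hull covers must be in the mask
    covered = queries[inside_hull]
    assert len(covered) > 0
    assert mask[covered[:, 0], covered[:, 1]].all()


def test_all_dense_slice_yields_empty_mask_with_warning():
    with pytest.warns(EmptyMaskWarning):
        mask = segment_lungs(np.full((20, 20), 400.0))
    assert not mask.any()


def test_lung_mask_invariant_to_zero_offset_and_hull_superset():
    sl, left, right = _two_lung_slice(bump=True)
    m1 = segment_lungs(sl)
    m2 = segment_lungs(sl + 0.0)
    assert np.array_equal(m1, m2)
    # hulled mask must contain the raw thresholded interior components
    pre = (sl < -320)
    pre_interior = pre.copy()
    pre_interior[0, :] = pre_interior[-1, :] = False
    pre_interior[:, 0] = pre_interior[:, -1] = False
    assert (m1 | ~pre_interior).all()


# ---------------------------------------------------------------- normalize


@pytest.mark.parametrize(
    "hu,expected",
    [(-1000.0, 0.0), (400.0, 1.0), (-300.0, 0.5), (-2000.0, 0.0), (1000.0, 1.0)],
)
def test_normalize_hu_linear_map_and_clipping(hu, expected):
    assert normalize_hu(np.array([[hu]]))[0, 0] == pytest.approx(expected)


def test_normalize_hu_monotone(rng):
    hu = rng.uniform(-1500, 800, size=100)
    hu.sort()
    out = normalize_hu(hu[None])
    assert (np.diff(out[0]) >= 0).all()


@settings(max_examples=50, derandomize=True)
@given(st.floats(min_value=-1000.0, max_value=400.0))
def test_normalize_hu_idempotent_through_inverse_map(hu):
    # mapping back to HU and re-normalizing reproduces the value
    v = normalize_hu(np.array([[hu]]))[0, 0]
    hu_back = v * 1400.0 - 1000.0
    assert normalize_hu(np.array([[hu_back]]))[0, 0] == pytest.approx(v, abs=1e-12)


# ---------------------------------------------------------------- crop


def test_crop_side_length_and_centering():
    sl = np.zeros((200, 200))
    sl[100, 100] = 1.0
    img = crop_nodule(sl, None, 100, 100, diameter_mm=10, spacing=0.5)
    assert img.intensity.shape == (40, 40)
    assert img.intensity[20, 20] == 1.0  # center pixel is the centroid

    img20 = crop_nodule(sl, None, 100, 100, diameter_mm=20, spacing=0.5)
    assert img20.intensity.shape == (80, 80)
    assert img20.intensity[40, 40] == 1.0


def test_crop_at_corner_is_zero_padded_and_recorded():
    sl = np.full((100, 100), 0.5)
    img = crop_nodule(sl, None, 0, 0, diameter_mm=10, spacing=0.5)
    assert img.intensity.shape == (40, 40)
    assert img.provenance["zero_padded"]
    assert img.intensity[0, 0] == 0.0  # out-of-bounds corner
    assert img.intensity[30, 30] == 0.5  # in-bounds region preserved


def test_crop_rejects_centroid_outside_slice():
    with pytest.raises(ValueError):
        crop_nodule(np.zeros((50, 50)), None, 60, 10, diameter_mm=5, spacing=0.5)


def test_crop_mask_cropped_identically():
    sl = np.full((100, 100), 0.3)
    mask = np.zeros((100, 100), bool)
    mask[40:60, 40:60] = True
    img = crop_nodule(sl, mask, 50, 50, diameter_mm=5, spacing=0.5)
    assert img.lung_mask.shape == img.intensity.shape
    assert img.lung_mask[10, 10]  # crop center is inside the mask block


# ---------------------------------------------------------------- end to end


def test_prepare_nodule_image_full_chain():
    from fmmseg.preprocess import prepare_nodule_image

    sl, left, right = _two_lung_slice()
    # a 6 px (~6 mm at 1 mm/px) soft-tissue nodule inside the right lung
    yy, xx = np.mgrid[0:80, 0:80]
    sl[np.hypot(yy - 40, xx - 58) < 3] = 40.0
    vol = CTVolume(np.stack([sl, sl]), spacing=(1.0, 1.0, 1.0))
    ann = NoduleAnnotation((0, 40, 58), diameter_mm=6.0)
    img = prepare_nodule_image(vol, ann, target_spacing=0.5)
    assert img.spacing == 0.5
    assert img.intensity.shape == (24, 24)  # 2 * 6 mm / 0.5 mm/px
    assert img.lung_mask is not None
    # crop center carries the (bright) nodule, normalized near 40 HU
    assert img.intensity[12, 12] > 0.6
    assert img.lung_mask[12, 12]


# ---------------------------------------------------------------- dicom


def test_dicom_series_roundtrip(tmp_path):
    """A minimal 2-slice synthetic CT series reads back in HU with correct
    spacing and slice order."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    arr = np.arange(16 * 16, dtype=np.int16).reshape(16, 16)
    for k, z in enumerate([7.5, 5.0]):  # written out of order on purpose
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Rows = ds.Columns = 16
        ds.PixelSpacing = [0.7, 0.7]
        ds.ImagePositionPatient = [0.0, 0.0, z]
        ds.RescaleSlope = 2.0
        ds.RescaleIntercept = -1024.0
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = (arr + k).tobytes()
        ds.save_as(tmp_path / f"s{k}.dcm", enforce_file_format=True)

    vol = read_dicom_series(tmp_path)
    assert vol.voxels.shape == (2, 16, 16)
    assert vol.spacing == (2.5, 0.7, 0.7)
    # slice at z=5.0 (written second, value arr+1) must come first
    assert vol.voxels[0, 0, 0] == pytest.approx((0 + 1) * 2.0 - 1024.0)
    assert vol.voxels[1, 0, 0] == pytest.approx(0 * 2.0 - 1024.0)
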