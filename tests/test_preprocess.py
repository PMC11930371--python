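"""Preprocessing pipeline: HU windowing, channel assembly, augmentation,
patch extraction, case-level splitting and image IO round trips."""

import numpy as np
import pytest

from cseanet import preprocess as pp
from cseanet.errors import ConfigurationError


def _slice(data):
    return pp.CTSlice(np.asarray(data, dtype=np.float32))


def test_clip_hu_window_endpoints():
    out = pp.clip_hu(_slice([[-1200.0, 1000.0, 5.0]])).data
    np.testing.assert_allclose(out, [[-1000.0, 800.0, 5.0]])


def test_clip_hu_idempotent_and_nonfinite(rng):
    x = rng.normal(0, 2000, size=(20, 20)).astype(np.float32)
    x[0, 0] = np.nan
    x[1, 1] = np.inf
    once = pp.clip_hu(_slice(x)).data
    twice = pp.clip_hu(pp.CTSlice(once)).data
    np.testing.assert_array_equal(once, twice)
    # every non-finite pixel (nan or inf) is replaced by the air value
    assert once[0, 0] == -1000.0 and once[1, 1] == -1000.0


def test_normalize_window_endpoints_and_midpoint():
    out = pp.normalize(_slice([[-1000.0, -100.0, 800.0]]))
    np.testing.assert_allclose(out, [[0.0, 0.5, 1.0]], atol=1e-7)


def test_normalize_monotone(rng):
    v = np.sort(rng.uniform(-1000, 800, size=50)).astype(np.float32)
    n = pp.normalize(_slice(v[None]))
    assert np.all(np.diff(n[0]) >= 0)


def test_to_three_channel_replicate(rng):
    x = rng.random((7, 9)).astype(np.float32)
    out = pp.to_three_channel(x)
    assert out.shape == (3, 7, 9)
    for c in range(3):
        np.testing.assert_array_equal(out[c], x)


def test_to_three_channel_adjacent_slices(rng):
    vol = rng.random((5, 4, 4)).astype(np.float32)
    mid = pp.to_three_channel(None, volume=vol, index=2)
    np.testing.assert_array_equal(mid, vol[1:4])
    end = pp.to_three_channel(None, volume=vol, index=0)
    np.testing.assert_array_equal(end, vol[[0, 0, 1]])


def test_hsv_augment_zero_strength_is_identity(rng):
    img = rng.random((3, 16, 16)).astype(np.float32)
    out = pp.hsv_luminance_augment(img, strength=0.0, rng=np.random.default_rng(0))
    np.testing.assert_allclose(out, img, atol=1e-6)


def test_hsv_augment_seed_reproducible(rng):
    img = rng.random((3, 16, 16)).astype(np.float32)
    a = pp.hsv_luminance_augment(img, 0.3, np.random.default_rng(5))
    b = pp.hsv_luminance_augment(img, 0.3, np.random.default_rng(5))
    np.testing.assert_array_equal(a, b)
    c = pp.hsv_luminance_augment(img, 0.3, np.random.default_rng(6))
    assert not np.array_equal(a, c)


def test_hsv_augment_stays_in_unit_range(rng):
    for _ in range(100):
        img = rng.random((3, 8, 8)).astype(np.float32)
        out = pp.hsv_luminance_augment(img, 0.4, rng)
        assert out.min() >= 0.0 and out.max() <= 1.0


def test_extract_patches_cover_small_nodule(rng):
    img = np.full((300, 300), -800.0, dtype=np.float32)
    mask = np.zeros((300, 300), dtype=np.uint8)
    mask[150:155, 200:205] = 1  # one 5-px nodule
    recs = pp.extract_patches(img, mask, n=4, size=224, rng=np.random.default_rng(3))
    assert len(recs) == 4
    for r in recs:
        assert pp.crop_patch(mask, r, 224).sum() > 0


def test_extract_patches_exact_fit_single_window(rng):
    img = np.zeros((224, 224), dtype=np.float32)
    mask = np.zeros((224, 224), dtype=np.uint8)
    mask[100, 100] = 1
    recs = pp.extract_patches(img, mask, n=4, size=224, rng=rng)
    assert all((r.row, r.col) == (0, 0) for r in recs)


def test_extract_patches_pads_small_inputs(rng):
    img = np.full((100, 100), -800.0, dtype=np.float32)
    mask = np.zeros((100, 100), dtype=np.uint8)
    recs = pp.extract_patches(img, mask, n=4, size=224, rng=rng)
    assert all((r.row, r.col) == (0, 0) for r in recs)


def test_extract_patches_windows_inside_bounds(rng):
    img = np.full((260, 310), -700.0, dtype=np.float32)
    mask = (rng.random((260, 310)) < 0.001).astype(np.uint8)
    recs = pp.extract_patches(img, mask, n=4, size=224, rng=rng)
    for r in recs:
        assert 0 <= r.row <= 260 - 224 and 0 <= r.col <= 310 - 224


def _records(n_cases, per_case=4):
    return [pp.SampleRecord(case_id=f"case{c}", image=f"i{c}_{k}.png", mask=f"m{c}_{k}.png")
            for c in range(n_cases) for k in range(per_case)]


def test_split_ten_cases_is_7_2_1():
    out = pp.split_dataset(_records(10), seed=4)
    cases = {s: {r.case_id for r in out if r.split == s} for s in ("train", "test", "val")}
    assert (len(cases["train"]), len(cases["test"]), len(cases["val"])) == (7, 2, 1)


def test_split_deterministic_and_disjoint():
    a = pp.split_dataset(_records(23), seed=9)
    b = pp.split_dataset(_records(23), seed=9)
    assert [(r.case_id, r.split) for r in a] == [(r.case_id, r.split) for r in b]
    by_split = {s: {r.case_id for r in a if r.split == s} for s in ("train", "test", "val")}
    assert not (by_split["train"] & by_split["test"])
    assert not (by_split["train"] & by_split["val"])
    assert not (by_split["test"] & by_split["val"])


def test_split_requires_three_cases():
    with pytest.raises(ConfigurationError, match="3"):
        pp.split_dataset(_records(2), seed=0)


def test_pipeline_maps_into_unit_cube(rng):
    raw = rng.normal(0, 3000, size=(32, 32)).astype(np.float32)
    x = pp.to_three_channel(pp.normalize(pp.clip_hu(_slice(raw))))
    assert x.shape == (3, 32, 32)
    assert x.min() >= 0.0 and x.max() <= 1.0


# -- IO -------------------------------------------------------------------


def test_mask_png_round_trip(tmp_path, rng):
    mask = (rng.random((30, 40)) < 0.3).astype(np.uint8)
    path = tmp_path / "m.png"
    pp.write_mask(path, mask)
    np.testing.assert_array_equal(pp.read_mask(path), mask)


def test_mask_nifti_round_trip_preserves_affine(tmp_path, rng):
    import nibabel as nib

    mask = (rng.random((12, 12)) < 0.5).astype(np.uint8)
    affine = np.diag([2.0, 3.0, 1.0, 1.0])
    path = tmp_path / "m.nii"
    pp.write_mask(path, mask, affine=affine)
    np.testing.assert_array_equal(pp.read_mask(path), mask)
    np.testing.assert_array_equal(nib.load(str(path)).affine, affine)


def test_png16_hu_round_trip(tmp_path, rng):
    from PIL import Image

    hu = rng.uniform(-1000, 800, size=(25, 25)).astype(np.float32)
    path = tmp_path / "ct.png"
    Image.fromarray(pp.hu_to_png16(hu)).save(path)
    back = pp.read_image(path)
    # 16-bit quantization of an 1800-HU window is ~0.03 HU per step
    np.testing.assert_allclose(back.data, hu, atol=0.05)


def test_dicom_rescale_recovers_hu(tmp_path):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(tmp_path / "s.dcm"), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.Rows = ds.Columns = 4
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = -1024.0
    ds.PixelData = np.full((4, 4), 1024, dtype=np.uint16).tobytes()
    ds.save_as(str(tmp_path / "s.dcm"))
    ct = pp.read_image(tmp_path / "s.dcm")
    np.testing.assert_allclose(ct.data, 0.0)  # stored 1024, intercept -1024 -> 0 HU


def test_nifti_volume_reader_returns_slices(tmp_path, rng):
    import nibabel as nib

    vol = rng.normal(size=(8, 8, 3)).astype(np.float32)
    path = tmp_path / "v.nii"
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))
    slices = pp.read_image(path)
    assert len(slices) == 3
    np.testing.assert_allclose(slices[1].data, vol[..., 1])


def test_unknown_extension_rejected(tmp_path):
    p = tmp_path / "x.bmp"
    p.write_bytes(b"")
    with pytest.raises(ValueError, match="unsupported"):
        pp.read_image(p)
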