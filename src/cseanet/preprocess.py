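"""CT preprocessing pipeline.

Hounsfield-unit intensities are clipped to the fixed window [-1000, 800] HU
(air to just above soft tissue/contrast), min-max normalized over that
window — not per image, so intensities stay comparable across scans — and
replicated (or stacked from adjacent slices) into a 3-channel tensor for the
network. Training images may additionally receive an HSV luminance/contrast
jitter, and 224x224 patches are cropped restrictively around regions of
interest. Datasets are split 7:2:1 (train:test:val) at the case level so
patches from one scan never straddle splits.

Readers/writers cover NIfTI, DICOM series and PNG. PNG grayscale values are
assumed to be the HU window mapped linearly onto the full integer range of
the bit depth (0 -> -1000 HU, max -> 800 HU).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import color as skcolor

from .errors import ConfigurationError, ShapeError

logger = logging.getLogger(__name__)

HU_MIN = -1000.0
HU_MAX = 800.0
HU_SPAN = HU_MAX - HU_MIN
LUNG_FIELD_THRESHOLD = -950.0  # pixels above this count as body/lung tissue


@dataclass
class CTSlice:
    """A single 2-D CT slice in Hounsfield units."""

    data: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    source: str = ""
    index: int = 0
    affine: np.ndarray | None = None

    @property
    def shape(self):
        return self.data.shape


@dataclass
class SampleRecord:
    """One training/evaluation sample: an aligned image/mask patch."""

    case_id: str
    image: str
    mask: str
    split: str = ""
    row: int = 0
    col: int = 0


# -- intensity pipeline ---------------------------------------------------


def clip_hu(ct: CTSlice) -> CTSlice:
    """Clamp to [-1000, 800] HU; non-finite pixels become -1000 (logged)."""
    data = np.asarray(ct.data, dtype=np.float32)
    bad = ~np.isfinite(data)
    if bad.any():
        logger.warning("%s: replaced %d non-finite pixels with %.0f HU",
                       ct.source, int(bad.sum()), HU_MIN)
        data = np.where(bad, HU_MIN, data)
    return replace(ct, data=np.clip(data, HU_MIN, HU_MAX))


def normalize(ct: CTSlice) -> np.ndarray:
    """Map the fixed HU window linearly onto [0, 1]."""
    return ((np.asarray(ct.data, dtype=np.float32) - HU_MIN) / HU_SPAN).astype(np.float32)


def to_three_channel(norm_slice: np.ndarray, volume: np.ndarray | None = None,
                     index: int | None = None) -> np.ndarray:
    """Assemble a (3, H, W) input.

    Default mode replicates the slice three times. When a normalized volume
    (Z, H, W) and a slice index are given, channels are the (k-1, k, k+1)
    neighbours, with edge replication at the volume ends.
    """
    if volume is not None:
        if index is None:
            raise ValueError("adjacent-slice mode needs the slice index")
        z = volume.shape[0]
        lo, hi = index - 1, index + 1
        if lo < 0 or hi >= z:
            logger.info("adjacent-slice mode at volume end: edge-replicating")
        idx = [int(np.clip(i, 0, z - 1)) for i in (lo, index, hi)]
        return np.stack([volume[i] for i in idx], axis=0).astype(np.float32)
    arr = np.asarray(norm_slice, dtype=np.float32)
    if arr.ndim != 2:
        raise ShapeError(f"expected a 2-D slice, got shape {arr.shape}")
    return np.stack([arr, arr, arr], axis=0)


def hsv_luminance_augment(rgb_image: np.ndarray, strength: float = 0.2,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Jitter saturation/value in HSV space and apply a contrast factor.

    The three multiplicative factors are drawn uniformly from
    [1 - strength, 1 + strength]; output is clamped back to [0, 1].
    Deterministic for a given generator state.
    """
    rng = rng or np.random.default_rng()
    img = np.asarray(rgb_image, dtype=np.float64)
    chw = img.shape[0] == 3 and img.ndim == 3
    hwc = img.transpose(1, 2, 0) if chw else img
    if strength < 0:
        raise ValueError("strength must be >= 0")
    s_fac, v_fac, c_fac = rng.uniform(1.0 - strength, 1.0 + strength, size=3)
    hsv = skcolor.rgb2hsv(hwc)
    hsv[..., 1] = np.clip(hsv[..., 1] * s_fac, 0.0, 1.0)
    hsv[..., 2] = np.clip(hsv[..., 2] * v_fac, 0.0, 1.0)
    out = skcolor.hsv2rgb(hsv)
    out = np.clip((out - out.mean()) * c_fac + out.mean(), 0.0, 1.0)
    out = out.astype(np.float32)
    return out.transpose(2, 0, 1) if chw else out


# -- patching -------------------------------------------------------------


def _pad_to(image: np.ndarray, mask: np.ndarray, size: int, fill: float):
    H, W = image.shape[-2:]
    ph, pw = max(size - H, 0), max(size - W, 0)
    if ph or pw:
        logger.info("padding %dx%d input to fit %d patches", H, W, size)
        spec = [(0, 0)] * (image.ndim - 2) + [(0, ph), (0, pw)]
        image = np.pad(image, spec, constant_values=fill)
        mask = np.pad(mask, [(0, ph), (0, pw)])
    return image, mask


def extract_patches(image: np.ndarray, mask: np.ndarray, n: int = 4, size: int = 224,
                    rng: np.random.Generator | None = None,
                    case_id: str = "", image_path: str = "", mask_path: str = "",
                    hu_image: bool = True) -> list[SampleRecord]:
    """Restrictive ROI cropping: n windows of size*size, each containing mask
    foreground when there is any, else restricted to the body/lung field.

    ``hu_image`` states whether intensities are HU (pad fill -1000 and lung
    field above -950 HU) or already normalized (fill 0, field above ~0.028).
    Returns SampleRecords carrying the patch origins (top-left, half-open
    windows); the caller crops with :func:`crop_patch`.
    """
    rng = rng or np.random.default_rng()
    fill = HU_MIN if hu_image else 0.0
    field_thr = LUNG_FIELD_THRESHOLD if hu_image else (LUNG_FIELD_THRESHOLD - HU_MIN) / HU_SPAN
    mask = np.asarray(mask)
    image, mask = _pad_to(np.asarray(image), mask, size, fill)
    H, W = mask.shape
    max_r, max_c = H - size, W - size
    fg = np.argwhere(mask > 0)
    records = []
    for _ in range(n):
        if len(fg):
            cy, cx = fg[rng.integers(len(fg))]
            jitter = size // 4
            r = int(np.clip(cy - size // 2 + rng.integers(-jitter, jitter + 1), 0, max_r))
            c = int(np.clip(cx - size // 2 + rng.integers(-jitter, jitter + 1), 0, max_c))
            # guarantee the sampled foreground pixel stays inside the window
            r = int(np.clip(r, max(cy - size + 1, 0), min(cy, max_r)))
            c = int(np.clip(c, max(cx - size + 1, 0), min(cx, max_c)))
        else:
            plane = image[0] if image.ndim == 3 else image
            body = np.argwhere(plane > field_thr)
            if len(body):
                cy, cx = body[rng.integers(len(body))]
                r = int(np.clip(cy - size // 2, 0, max_r))
                c = int(np.clip(cx - size // 2, 0, max_c))
            else:
                r = int(rng.integers(0, max_r + 1))
                c = int(rng.integers(0, max_c + 1))
        records.append(SampleRecord(case_id=case_id, image=image_path, mask=mask_path,
                                    row=r, col=c))
    return records


def crop_patch(array: np.ndarray, record: SampleRecord, size: int = 224) -> np.ndarray:
    """Crop the half-open window [row, row+size) x [col, col+size)."""
    r, c = record.row, record.col
    return array[..., r : r + size, c : c + size]


# -- splitting ------------------------------------------------------------


def split_dataset(records: list[SampleRecord], ratios: tuple[int, int, int] = (7, 2, 1),
                  seed: int = 0) -> list[SampleRecord]:
    """Assign train/test/val split labels by case (largest-remainder 7:2:1).

    All records of one case land in the same split; assignment is a seeded
    shuffle of the case list, so it is deterministic and leakage-free.
    """
    if not records:
        raise ValueError("cannot split an empty record list")
    cases = sorted({r.case_id for r in records})
    if len(cases) < 3:
        raise ConfigurationError(
            f"need at least 3 cases for a 3-way split, got {len(cases)}"
        )
    rng = np.random.default_rng(seed)
    order = [cases[i] for i in rng.permutation(len(cases))]
    total = sum(ratios)
    n = len(order)
    quotas = [n * r / total for r in ratios]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = np.array(quotas) - np.array(counts)
    while sum(counts) < n:
        i = int(np.argmax(remainders))
        counts[i] += 1
        remainders[i] = -1
    labels = {}
    start = 0
    for name, cnt in zip(("train", "test", "val"), counts):
        for cid in order[start : start + cnt]:
            labels[cid] = name
        start += cnt
    return [replace(r, split=labels[r.case_id]) for r in records]


# -- IO -------------------------------------------------------------------


def _png_to_hu(arr: np.ndarray, bits: int) -> np.ndarray:
    return (arr.astype(np.float32) / float(2 ** bits - 1)) * HU_SPAN + HU_MIN


def hu_to_png16(data: np.ndarray) -> np.ndarray:
    """Map [-1000, 800] HU linearly onto uint16 (the PNG storage contract)."""
    frac = np.clip((np.asarray(data, np.float64) - HU_MIN) / HU_SPAN, 0.0, 1.0)
    return np.round(frac * 65535.0).astype(np.uint16)


def read_image(path) -> CTSlice | list[CTSlice]:
    """Read a CT slice or volume from NIfTI, a DICOM file/series dir, or PNG.

    DICOM rescale slope/intercept is applied to recover HU; PNG values are
    interpreted per the linear HU-window contract of this module.
    """
    path = Path(path)
    name = path.name.lower()
    if path.is_dir():
        import pydicom

        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima", ""))
        if not files:
            raise ValueError(f"no DICOM files in series directory {path}")
        slices = []
        datasets = [pydicom.dcmread(str(f)) for f in files]
        shapes = {ds.pixel_array.shape for ds in datasets}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent DICOM series geometry in {path}: {shapes}")
        datasets.sort(key=lambda ds: float(getattr(ds, "InstanceNumber", 0)))
        for k, ds in enumerate(datasets):
            slices.append(_dicom_to_slice(ds, str(path), k))
        return slices
    if name.endswith(".dcm"):
        import pydicom

        return _dicom_to_slice(pydicom.dcmread(str(path)), str(path), 0)
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float32)
        zooms = img.header.get_zooms()
        spacing = (float(zooms[0]), float(zooms[1])) if len(zooms) >= 2 else (1.0, 1.0)
        if data.ndim == 2:
            return CTSlice(data, spacing, str(path), 0, np.asarray(img.affine))
        return [CTSlice(data[..., k], spacing, str(path), k, np.asarray(img.affine))
                for k in range(data.shape[-1])]
    if name.endswith(".png"):
        img = Image.open(path)
        arr = np.asarray(img)
        bits = 16 if arr.dtype == np.uint16 else 8
        return CTSlice(_png_to_hu(arr, bits), (1.0, 1.0), str(path), 0)
    raise ValueError(f"unsupported image format: {path}")


def _dicom_to_slice(ds, source: str, index: int) -> CTSlice:
    arr = ds.pixel_array.astype(np.float32)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    spacing = tuple(float(s) for s in getattr(ds, "PixelSpacing", (1.0, 1.0)))
    return CTSlice(arr * slope + intercept, spacing, source, index)


def write_mask(path, mask: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write a binary mask as 0/255 PNG or 0/1 NIfTI (preserving the affine)."""
    path = Path(path)
    m = (np.asarray(mask) > 0).astype(np.uint8)
    name = path.name.lower()
    if name.endswith(".png"):
        Image.fromarray(m * 255, mode="L").save(path)
    elif name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        aff = affine if affine is not None else np.eye(4)
        nib.save(nib.Nifti1Image(m, aff), str(path))
    else:
        raise ValueError(f"unsupported mask format: {path}")


def read_mask(path) -> np.ndarray:
    """Read a binary mask written by :func:`write_mask`."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith(".png"):
        return (np.asarray(Image.open(path)) > 127).astype(np.uint8)
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        return (np.asanyarray(nib.load(str(path)).dataobj) > 0).astype(np.uint8)
    raise ValueError(f"unsupported mask format: {path}")
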