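"""Synthetic CT-slice phantom generator.

Each phantom slice is a soft-tissue field (~+40 HU) containing two
elliptical lung fields (~-800 HU) in which a small number of bright
(~0 HU), star-convex nodules are placed. Nodule boundaries are irregular:
the radius is modulated by a low-order random harmonic series, emulating
the blurred, lobulated margins that make real nodules hard to delineate.
The rendered image is Gaussian-blurred (partial-volume soft edges) and
carries additive Gaussian HU noise; the ground-truth mask is the exact
pre-blur nodule support, mirroring how annotators draw crisp contours over
soft image edges.

The generator is fully determined by a :class:`PhantomSpec` and a seed, and
its outputs stay inside the [-1000, 800] HU window, so the preprocessing
clip is lossless on phantom data. What it deliberately does not emulate:
ribs, vessels, airways, scanner reconstruction kernels, or 3-D continuity.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .preprocess import CTSlice, SampleRecord, hu_to_png16
from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class PhantomSpec:
    """Parameters of the synthetic slice generator (HU levels and geometry)."""

    size: tuple[int, int] = (96, 96)
    nodule_count: tuple[int, int] = (1, 3)
    nodule_radius: tuple[float, float] = (3.0, 10.0)
    irregularity: float = 0.25          # radial modulation, fraction of radius
    lung_hu: float = -800.0
    tissue_hu: float = 40.0
    nodule_hu: float = 0.0
    nodule_hu_jitter: float = 30.0
    noise_sigma: float = 20.0           # additive Gaussian noise, HU
    blur_sigma: float = 1.0             # partial-volume edge softening, px
    max_placement_tries: int = 50

    def __post_init__(self):
        if self.nodule_radius[0] < 2:
            raise ConfigurationError("nodule radii must be >= 2 px")
        if self.nodule_count[0] > self.nodule_count[1]:
            raise ConfigurationError("nodule_count must be (min, max) with min <= max")


def _lung_fields(shape: tuple[int, int]) -> np.ndarray:
    """Two elliptical lung fields, mirrored about the midline."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    cy = H * 0.52
    ry, rx = H * 0.36, W * 0.20
    left = ((yy - cy) / ry) ** 2 + ((xx - W * 0.28) / rx) ** 2 <= 1.0
    right = ((yy - cy) / ry) ** 2 + ((xx - W * 0.72) / rx) ** 2 <= 1.0
    return left | right


def _star_convex_blob(shape: tuple[int, int], center: tuple[float, float],
                      radius: float, irregularity: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Rasterize a star-convex region r(theta) = R(1 + sum_k a_k harmonics)."""
    H, W = shape
    n_harm = 4
    amps = rng.uniform(-1.0, 1.0, size=n_harm)
    phases = rng.uniform(0.0, 2 * np.pi, size=n_harm)
    if np.abs(amps).sum() > 0:
        amps = amps / np.abs(amps).sum() * irregularity
    yy, xx = np.mgrid[0:H, 0:W]
    dy, dx = yy - center[0], xx - center[1]
    rr = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_theta = radius * (1.0 + sum(a * np.cos((k + 2) * theta + p)
                                  for k, (a, p) in enumerate(zip(amps, phases))))
    return rr <= r_theta


def generate_slice(spec: PhantomSpec, rng: np.random.Generator) -> tuple[CTSlice, np.ndarray]:
    """Generate one (CT slice, binary mask) pair; deterministic per rng state."""
    H, W = spec.size
    lungs = _lung_fields((H, W))
    levels = np.where(lungs, spec.lung_hu, spec.tissue_hu).astype(np.float64)
    mask = np.zeros((H, W), dtype=np.uint8)

    n_target = int(rng.integers(spec.nodule_count[0], spec.nodule_count[1] + 1))
    # lung interior eroded by the max radius keeps nodules fully in-field
    placed = 0
    for _ in range(n_target):
        ok = False
        for _try in range(spec.max_placement_tries):
            radius = float(rng.uniform(*spec.nodule_radius))
            margin = int(np.ceil(radius * (1.0 + spec.irregularity))) + 1
            interior = ndimage.binary_erosion(lungs, iterations=margin)
            cand = np.argwhere(interior & (mask == 0))
            if not len(cand):
                continue
            cy, cx = cand[rng.integers(len(cand))]
            blob = _star_convex_blob((H, W), (float(cy), float(cx)), radius,
                                     spec.irregularity, rng)
            blob &= lungs
            if blob.any():
                hu = spec.nodule_hu + rng.uniform(-spec.nodule_hu_jitter, spec.nodule_hu_jitter)
                levels = np.where(blob, hu, levels)
                mask[blob] = 1
                ok = True
                break
        placed += int(ok)
    if placed < n_target:
        logger.info("placed %d of %d nodules (placement retries exhausted)", placed, n_target)

    img = levels
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, -1000.0, 800.0).astype(np.float32)
    return CTSlice(img, (1.0, 1.0), "phantom", 0), mask


def generate_dataset(n_slices: int, spec: PhantomSpec, out_dir, seed: int = 0,
                     fmt: str = "png") -> list[SampleRecord]:
    """Write ``n_slices`` image/mask pairs plus a manifest CSV.

    Per-slice seeds are ``seed + index`` so any slice can be regenerated in
    isolation; with fixed encoder settings the files are byte-reproducible.
    Returns the manifest records (split labels unassigned).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt not in ("png", "nifti"):
        raise ValueError(f"format must be png or nifti, got {fmt!r}")
    records = []
    for k in range(n_slices):
        rng = np.random.default_rng(seed + k)
        ct, mask = generate_slice(spec, rng)
        stem = f"slice_{k:04d}"
        if fmt == "png":
            img_path = out_dir / f"{stem}_img.png"
            mask_path = out_dir / f"{stem}_mask.png"
            Image.fromarray(hu_to_png16(ct.data)).save(img_path)
            Image.fromarray(mask * 255, mode="L").save(mask_path)
        else:
            import nibabel as nib

            img_path = out_dir / f"{stem}_img.nii"
            mask_path = out_dir / f"{stem}_mask.nii"
            nib.save(nib.Nifti1Image(ct.data, np.eye(4)), str(img_path))
            nib.save(nib.Nifti1Image(mask, np.eye(4)), str(mask_path))
        records.append(SampleRecord(case_id=stem, image=str(img_path),
                                    mask=str(mask_path)))
    write_manifest(out_dir / "manifest.csv", records)
    return records


MANIFEST_COLUMNS = ("case_id", "image", "mask", "split", "row", "col")


def write_manifest(path, records: list[SampleRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for r in records:
            writer.writerow([r.case_id, r.image, r.mask, r.split, r.row, r.col])


def read_manifest(path) -> list[SampleRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(SampleRecord(case_id=row["case_id"], image=row["image"],
                                        mask=row["mask"], split=row["split"],
                                        row=int(row["row"] or 0), col=int(row["col"] or 0)))
    return records
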