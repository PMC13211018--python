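"""Synthetic desk-scale segmentation datasets and raster I/O.

Two generators emulate the statistical structure of common 2-D medical
segmentation tasks:

* ``make_lesion_dataset`` — dermoscopy-style binary data: one irregular
  soft-edged blob (a periodic-spline perturbation of a disc) darker than a
  textured background, with multiplicative speckle.  The mask is the blob
  interior; the per-image foreground fraction is kept inside (0.05, 0.6).
* ``make_organ_phantom_dataset`` — CT/MRI-slice-style multi-class phantoms:
  several non-overlapping elliptical organs with distinct intensity bands,
  one of them ring-shaped (an annulus, mimicking myocardium-like topology),
  on a noisy background.  Label 0 is background.

Determinism: sample ``i`` of a dataset with seed ``s`` is generated from
``default_rng([s, i])``, so datasets are reproducible and prefix-stable
(the first k samples are identical for any larger n).

Images are stored as 8-bit PNGs in [0, 255]; masks as single-channel 8-bit
PNGs holding raw integer labels (no value scaling), so mask round-trips are
bit-exact.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

LESION_CONTRAST_RANGE = (0.25, 0.6)
LESION_FG_RANGE = (0.05, 0.6)
_MAX_TRIES = 64


@dataclass
class SampleRecord:
    """One image/mask pair plus the generator parameters that produced it."""

    image: np.ndarray  # (C, H, W) float in [0, 1]
    mask: np.ndarray   # (H, W) integer labels, 0 = background
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.image.shape[1:] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} / mask {self.mask.shape} size mismatch")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("image contains non-finite values")


def _check_size(size: int) -> None:
    if size < 32 or size % 32:
        raise ValueError(f"image size must be a positive multiple of 32, got {size}")


def _blob_mask(rng: np.random.Generator, size: int) -> np.ndarray:
    """Irregular blob: radius r(theta) from a periodic cubic spline through
    randomly perturbed control radii."""
    cy, cx = rng.uniform(0.38 * size, 0.62 * size, size=2)
    r0 = rng.uniform(0.15, 0.33) * size
    n_ctrl = rng.integers(6, 11)
    theta_c = np.linspace(0, 2 * math.pi, n_ctrl, endpoint=False)
    radii = r0 * rng.uniform(0.75, 1.25, size=n_ctrl)
    theta_ext = np.concatenate([theta_c, [2 * math.pi]])
    radii_ext = np.concatenate([radii, [radii[0]]])
    spline = CubicSpline(theta_ext, radii_ext, bc_type="periodic")
    yy, xx = np.mgrid[0:size, 0:size]
    theta = np.mod(np.arctan2(yy - cy, xx - cx), 2 * math.pi)
    rr = np.hypot(yy - cy, xx - cx)
    return (rr <= spline(theta)).astype(np.int64)


def make_lesion_sample(seed: int, index: int, size: int,
                       contrast_range=LESION_CONTRAST_RANGE,
                       channels: int = 3) -> SampleRecord:
    """One dermoscopy-like sample, deterministic in (seed, index)."""
    _check_size(size)
    for attempt in range(_MAX_TRIES):
        rng = np.random.default_rng([seed % (2**31), index, attempt])
        mask = _blob_mask(rng, size)
        frac = mask.mean()
        if LESION_FG_RANGE[0] + 0.01 < frac < LESION_FG_RANGE[1] - 0.05:
            break
    else:  # pragma: no cover - the blob family stays inside the band
        raise RuntimeError("could not place lesion within foreground band")
    lo, hi = contrast_range
    contrast = rng.uniform(lo, hi) if hi > lo else float(lo)
    base = rng.uniform(0.45, 0.7)
    texture = gaussian_filter(rng.standard_normal((size, size)), 3.0)
    texture = 0.06 * texture / max(texture.std(), 1e-8)
    soft = gaussian_filter(mask.astype(float), 1.5)  # soft lesion boundary
    img = base + texture - contrast * soft
    speckle = 1.0 + 0.05 * rng.standard_normal((size, size))
    img = img * speckle
    chans = []
    for c in range(channels):
        tint = 1.0 + 0.08 * rng.standard_normal()
        chans.append(np.clip(img * tint, 0.0, 1.0))
    image = np.stack(chans, axis=0)
    meta = {"task": "lesion", "seed": seed, "index": index, "size": size,
            "contrast": contrast, "fg_fraction": float(frac)}
    return SampleRecord(image=image, mask=mask, meta=meta)


def make_lesion_dataset(n: int, size: int, seed: int,
                        contrast_range=LESION_CONTRAST_RANGE,
                        channels: int = 3) -> list[SampleRecord]:
    """Binary lesion dataset; ``contrast_range=(0, 0)`` gives the
    null-signal control (images independent of masks)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [make_lesion_sample(seed, i, size, contrast_range, channels)
            for i in range(n)]


def _ellipse(yy, xx, cy, cx, ry, rx, angle) -> np.ndarray:
    ca, sa = math.cos(angle), math.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def make_organ_phantom_sample(seed: int, index: int, size: int,
                              num_classes: int) -> SampleRecord:
    """One multi-class phantom: K-1 disjoint organs, one of them a ring."""
    _check_size(size)
    if num_classes < 3:
        raise ValueError("organ phantoms need num_classes >= 3")
    rng = np.random.default_rng([seed % (2**31), index, 1_000_000])
    yy, xx = np.mgrid[0:size, 0:size]
    mask = np.zeros((size, size), dtype=np.int64)
    occupied = np.zeros((size, size), dtype=bool)
    annulus_class = 1  # first placed organ is the ring
    for cls in range(1, num_classes):
        placed = False
        for _ in range(_MAX_TRIES):
            cy, cx = rng.uniform(0.2 * size, 0.8 * size, size=2)
            ry = rng.uniform(0.08, 0.18) * size
            rx = rng.uniform(0.08, 0.18) * size
            ang = rng.uniform(0, math.pi)
            region = _ellipse(yy, xx, cy, cx, ry, rx, ang)
            if cls == annulus_class:
                inner = _ellipse(yy, xx, cy, cx, 0.55 * ry, 0.55 * rx, ang)
                footprint = region  # keep the hole free of other organs
                region = region & ~inner
            else:
                footprint = region
            if region.sum() < 16:
                continue
            if not (occupied & footprint).any():
                mask[region] = cls
                occupied |= footprint
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place organ {cls}: canvas too crowded for "
                f"{num_classes - 1} regions at size {size}")
    bands = np.linspace(0.25, 0.85, num_classes)
    img = np.full((size, size), 0.12)
    img += gaussian_filter(rng.standard_normal((size, size)), 4.0) * 0.05
    for cls in range(1, num_classes):
        img[mask == cls] = bands[cls] + 0.03 * rng.standard_normal()
    img += 0.03 * rng.standard_normal((size, size))
    image = np.clip(img, 0.0, 1.0)[None]
    meta = {"task": "organs", "seed": seed, "index": index, "size": size,
            "num_classes": num_classes, "annulus_class": annulus_class}
    return SampleRecord(image=image, mask=mask, meta=meta)


def make_organ_phantom_dataset(n: int, size: int, num_classes: int,
                               seed: int) -> list[SampleRecord]:
    if n < 1:
        raise ValueError("n must be >= 1")
    return [make_organ_phantom_sample(seed, i, size, num_classes)
            for i in range(n)]


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(sample: SampleRecord, seed: int) -> SampleRecord:
    """Random horizontal/vertical flips (p = 0.5 each) and a random multiple
    of 90 deg rotation, applied identically to image and mask.  Rotations
    are axis-aligned so masks stay integer with no interpolation."""
    rng = np.random.default_rng(seed % (2**31))
    img, mask = sample.image, sample.mask
    ops = {"hflip": False, "vflip": False, "rot90": 0}
    if rng.random() < 0.5:
        img, mask = img[:, :, ::-1], mask[:, ::-1]
        ops["hflip"] = True
    if rng.random() < 0.5:
        img, mask = img[:, ::-1, :], mask[::-1, :]
        ops["vflip"] = True
    k = int(rng.integers(0, 4))
    if k:
        img = np.rot90(img, k, axes=(1, 2))
        mask = np.rot90(mask, k)
        ops["rot90"] = k
    meta = dict(sample.meta)
    meta["augment"] = ops
    return SampleRecord(image=np.ascontiguousarray(img),
                        mask=np.ascontiguousarray(mask), meta=meta)


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

def write_dataset(directory, samples: list[SampleRecord],
                  splits: list[str] | None = None) -> None:
    """Write image_XXXX.png / mask_XXXX.png pairs plus manifest.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    splits = splits or ["train"] * len(samples)
    rows = []
    for i, (s, split) in enumerate(zip(samples, splits)):
        img8 = np.round(np.clip(s.image, 0, 1) * 255).astype(np.uint8)
        if img8.shape[0] == 1:
            pil_img = Image.fromarray(img8[0], mode="L")
        elif img8.shape[0] == 3:
            pil_img = Image.fromarray(np.transpose(img8, (1, 2, 0)), mode="RGB")
        else:
            raise ValueError(f"unsupported channel count {img8.shape[0]}")
        if s.mask.min() < 0 or s.mask.max() > 255:
            raise ValueError("mask labels must fit in 8 bits")
        pil_mask = Image.fromarray(s.mask.astype(np.uint8), mode="L")
        img_name, mask_name = f"image_{i:04d}.png", f"mask_{i:04d}.png"
        pil_img.save(directory / img_name)
        pil_mask.save(directory / mask_name)
        rows.append((img_name, mask_name, split))
    with open(directory / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image", "mask", "split"])
        w.writerows(rows)


def read_dataset(directory, num_classes: int | None = None,
                 split: str | None = None) -> list[SampleRecord]:
    """Read PNG pairs back: images scaled to [0, 1], masks as raw labels."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if manifest.exists():
        with open(manifest, newline="") as fh:
            rows = [r for r in csv.DictReader(fh)]
        if split is not None:
            rows = [r for r in rows if r["split"] == split]
        pairs = [(r["image"], r["mask"], r["split"]) for r in rows]
    else:
        images = sorted(p.name for p in directory.glob("image_*.png"))
        pairs = [(n, n.replace("image_", "mask_"), "train") for n in images]
    samples = []
    for img_name, mask_name, split_name in pairs:
        img_path, mask_path = directory / img_name, directory / mask_name
        if not img_path.exists():
            raise FileNotFoundError(f"missing image file {img_path}")
        if not mask_path.exists():
            raise FileNotFoundError(f"missing mask file {mask_path} "
                                    f"(pair of {img_name})")
        img = np.asarray(Image.open(img_path))
        if img.ndim == 2:
            image = img[None].astype(float) / 255.0
        else:
            image = np.transpose(img, (2, 0, 1)).astype(float) / 255.0
        mask = np.asarray(Image.open(mask_path)).astype(np.int64)
        if mask.ndim != 2:
            raise ValueError(f"mask {mask_path} is not single-channel")
        if image.shape[1:] != mask.shape:
            raise ValueError(f"size mismatch between {img_name} ({image.shape[1:]}) "
                             f"and {mask_name} ({mask.shape})")
        if num_classes is not None and mask.max() >= num_classes:
            raise ValueError(f"mask {mask_path} holds label {mask.max()} "
                             f">= num_classes={num_classes}")
        samples.append(SampleRecord(image=image, mask=mask,
                                    meta={"file": img_name, "split": split_name}))
    return samples
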