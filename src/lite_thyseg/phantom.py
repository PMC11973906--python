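"""Synthetic ultrasound phantoms with exact nodule ground truth.

Real thyroid ultrasound frames are greyscale, dominated by multiplicative
speckle, and contain zero or more hypoechoic (darker-than-background)
roughly elliptical nodules, sometimes with a posterior acoustic shadow.
The generator emulates exactly that structure: a smooth tissue background,
multiplicative speckle, rotated dark ellipses with a blurred rim, and an
optional vertical shadow band.  Because the generator knows the ellipses
analytically, the paired masks are pixel-exact, which lets metric and
training code be validated against known geometry.  The default dataset
composition mirrors a clinical collection of 247 images of which 154
contain nodules.

The goal is exercising the pipeline end to end, not acoustic fidelity:
there is no beam profile, attenuation or time-gain compensation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage

from .preprocess import ImageRecord

__all__ = ["PhantomSpec", "PhantomDataset", "generate_phantom", "generate_dataset",
           "save_dataset", "load_dataset"]

DEFAULT_PREVALENCE = 154 / 247


@dataclass(frozen=True)
class PhantomSpec:
    """Distributional description of the synthetic images."""

    size: int = 512
    nodule_count_range: Tuple[int, int] = (0, 2)
    radius_range: Tuple[float, float] = (15.0, 80.0)  # semi-axes at size=512
    intensity_drop_range: Tuple[float, float] = (30.0, 80.0)
    background_mean: float = 120.0
    speckle_sigma: float = 12.0
    speckle_model: str = "gaussian"  # or "rayleigh"
    shadow_prob: float = 0.15
    prevalence: float = DEFAULT_PREVALENCE

    def __post_init__(self):
        if self.nodule_count_range[0] > self.nodule_count_range[1]:
            raise ValueError("nodule_count_range must be ordered")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must be ordered")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if self.speckle_model not in ("gaussian", "rayleigh"):
            raise ValueError("speckle_model must be 'gaussian' or 'rayleigh'")


@dataclass
class PhantomDataset:
    records: List[ImageRecord]
    spec: PhantomSpec
    seed: int

    def __len__(self):
        return len(self.records)


def _ellipse_mask(size: int, cx: float, cy: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    x = xx - cx
    y = yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (x * ct + y * st) / a
    v = (-x * st + y * ct) / b
    return (u * u + v * v <= 1.0).astype(np.uint8)


def generate_phantom(spec: PhantomSpec, seed: int, *, record_id: str = "phantom",
                     with_nodules: bool | None = None) -> ImageRecord:
    """One speckled greyscale image with its exact binary nodule mask.

    ``with_nodules`` overrides the nodule count draw (used by
    :func:`generate_dataset` to pin the dataset prevalence exactly).
    """
    rng = np.random.default_rng(seed)
    n = spec.size
    scale = n / 512.0

    # smooth tissue background
    base = rng.normal(0.0, 1.0, (n, n))
    base = ndimage.gaussian_filter(base, sigma=40.0 * scale, mode="nearest")
    if base.std() > 0:
        base = base / base.std() * 8.0
    image = spec.background_mean + base

    lo, hi = spec.nodule_count_range
    if with_nodules is None:
        count = rng.integers(lo, hi + 1)
    elif with_nodules:
        count = rng.integers(max(lo, 1), hi + 1)
    else:
        count = 0

    mask = np.zeros((n, n), dtype=np.uint8)
    for _ in range(count):
        a = rng.uniform(*spec.radius_range) * scale
        b = rng.uniform(*spec.radius_range) * scale
        theta = rng.uniform(0.0, np.pi)
        half = max(a, b)
        if 2 * half >= n:
            raise ValueError(
                f"nodule semi-axis {half:.0f} px cannot fit a {n}-px frame")
        placed = False
        for _attempt in range(50):
            cx = rng.uniform(half, n - half)
            cy = rng.uniform(half, n - half)
            ell = _ellipse_mask(n, cx, cy, a, b, theta)
            if not (ell & mask).any():
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place a nodule after 50 attempts; "
                               "radius_range too large for the frame")
        drop = rng.uniform(*spec.intensity_drop_range)
        rim = ndimage.gaussian_filter(ell.astype(np.float64),
                                      sigma=max(1.5, 3.0 * scale))
        image = image - drop * rim
        mask |= ell
        if rng.random() < spec.shadow_prob:
            x0 = int(max(0, cx - a / 2))
            x1 = int(min(n, cx + a / 2))
            y0 = int(min(n - 1, cy + half))
            shade = np.linspace(0.25, 0.0, max(n - y0, 1))[:, None]
            image[y0:, x0:x1] *= 1.0 - shade

    # multiplicative speckle
    rel = spec.speckle_sigma / spec.background_mean
    if spec.speckle_model == "gaussian":
        field_ = rng.normal(1.0, rel, (n, n))
    else:  # Rayleigh speckle, rescaled to unit mean and matched spread
        sigma_r = rel / np.sqrt(4.0 / np.pi - 1.0)
        field_ = rng.rayleigh(sigma_r, (n, n))
        field_ = field_ / (sigma_r * np.sqrt(np.pi / 2.0))
    image = image * field_

    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return ImageRecord(image=image, mask=mask, id=record_id, provenance="original")


def generate_dataset(n: int, spec: PhantomSpec = PhantomSpec(),
                     seed: int = 0) -> PhantomDataset:
    """n phantoms with exactly ``round(n * prevalence)`` nodule-bearing images."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n_with = int(round(n * spec.prevalence))
    flags = np.zeros(n, dtype=bool)
    flags[rng.permutation(n)[:n_with]] = True
    width = len(str(n - 1))
    records = [
        generate_phantom(spec, seed=int(rng.integers(0, 2**31)),
                         record_id=f"phantom_{i:0{width}d}",
                         with_nodules=bool(flags[i]))
        for i in range(n)
    ]
    return PhantomDataset(records=records, spec=spec, seed=seed)


def save_dataset(dataset: PhantomDataset, out_dir: str | Path) -> Path:
    """Write image/mask PNG pairs plus a CSV manifest; returns manifest path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "image", "mask", "provenance", "has_nodule"])
        for rec in dataset.records:
            img_path = out / "images" / f"{rec.id}.png"
            mask_path = out / "masks" / f"{rec.id}.png"
            Image.fromarray(rec.image, mode="L").save(img_path)
            Image.fromarray(rec.mask * 255, mode="L").save(mask_path)
            writer.writerow([rec.id, img_path.name, mask_path.name,
                             rec.provenance, int(rec.mask.any())])
    return manifest


def load_dataset(manifest: str | Path) -> List[ImageRecord]:
    manifest = Path(manifest)
    root = manifest.parent
    records = []
    with open(manifest) as fh:
        for row in csv.DictReader(fh):
            image = np.asarray(Image.open(root / "images" / row["image"]).convert("L"))
            mask = (np.asarray(Image.open(root / "masks" / row["mask"]).convert("L"))
                    > 127).astype(np.uint8)
            records.append(ImageRecord(image=image, mask=mask, id=row["id"],
                                       provenance=row.get("provenance", "original")))
    return records
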