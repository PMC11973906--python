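"""Image standardization, enhancement, augmentation and dataset splitting.

The pipeline standardizes arbitrary greyscale or RGB ultrasound frames to
512x512 8-bit "mode L" images with nearest-neighbour-resized binary
masks, denoises with a Gaussian filter (ultrasound speckle is treated as
Gaussian noise), enhances contrast with CLAHE, quadruples the data by
mirroring and small random rotation, and splits 6:2:2 into
train/validation/test.  Augmentation happens before the split, so
augment-siblings of one source image can land in different partitions;
``split_grouped`` offers a leak-free alternative that keeps siblings
together.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import exposure, transform

__all__ = [
    "ImageRecord",
    "SplitSpec",
    "standardize",
    "gaussian_denoise",
    "clahe",
    "augment",
    "split",
    "split_grouped",
]

TARGET_SIZE = 512
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ImageRecord:
    """A greyscale image, its binary mask, and bookkeeping."""

    image: np.ndarray
    mask: np.ndarray
    id: str
    provenance: str = "original"

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"{self.id}: image {self.image.shape} and mask {self.mask.shape} differ")


@dataclass(frozen=True)
class SplitSpec:
    """Random-split description; ratios default to 6:2:2."""

    ratios: Tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self):
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


def _to_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 3:
        image = image[..., :3] @ _LUMA
    return image


def standardize(raw_image: np.ndarray, raw_mask: np.ndarray, *,
                record_id: str = "img", size: int = TARGET_SIZE) -> ImageRecord:
    """Resize to ``size`` x ``size`` 8-bit greyscale; re-binarize the mask."""
    image = _to_gray(raw_image)
    mask = np.asarray(raw_mask)
    if mask.ndim == 3:
        mask = mask[..., 0]
    if image.shape != mask.shape:
        raise ValueError(
            f"{record_id}: image {image.shape} and mask {mask.shape} differ")
    if image.shape != (size, size):
        image = transform.resize(image.astype(np.float64), (size, size),
                                 order=1, anti_aliasing=True, preserve_range=True)
        mask = transform.resize(mask, (size, size), order=0,
                                anti_aliasing=False, preserve_range=True)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    mask = (np.asarray(mask) > 0).astype(np.uint8)
    return ImageRecord(image=image, mask=mask, id=record_id, provenance="original")


def gaussian_denoise(record: ImageRecord, sigma: float = 1.0) -> ImageRecord:
    """Gaussian low-pass on the image only; the mask is untouched."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    smoothed = ndimage.gaussian_filter(record.image.astype(np.float64), sigma,
                                       mode="nearest")
    image = np.clip(np.rint(smoothed), 0, 255).astype(np.uint8)
    return replace(record, image=image)


def clahe(record: ImageRecord, clip_limit: float = 2.0,
          tile_grid: Tuple[int, int] = (8, 8)) -> ImageRecord:
    """Contrast-limited adaptive histogram equalization on the image.

    ``clip_limit`` follows the common histogram-multiple convention (2.0
    means clip at twice the uniform bin height over 256 bins); it is
    rescaled to the relative clip used by scikit-image.
    """
    h, w = record.image.shape
    if tile_grid[0] > h or tile_grid[1] > w:
        raise ValueError("tile grid is larger than the image")
    kernel = (max(1, h // tile_grid[0]), max(1, w // tile_grid[1]))
    out = exposure.equalize_adapthist(record.image, kernel_size=kernel,
                                      clip_limit=clip_limit / 256.0)
    image = np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
    return replace(record, image=image)


def _rotate(record: ImageRecord, angle: float, rid: str) -> ImageRecord:
    image = ndimage.rotate(record.image.astype(np.float64), angle, reshape=False,
                           order=1, mode="constant", cval=0.0)
    mask = ndimage.rotate(record.mask, angle, reshape=False, order=0,
                          mode="constant", cval=0)
    return ImageRecord(image=np.clip(np.rint(image), 0, 255).astype(np.uint8),
                       mask=(mask > 0).astype(np.uint8), id=rid,
                       provenance="rotated")


def augment(records: Sequence[ImageRecord], seed: int = 0) -> List[ImageRecord]:
    """Fourfold augmentation: original, mirrors, and a small seeded rotation.

    Per input record emits the original, its horizontal and vertical
    mirrors, and a rotation by an angle drawn uniformly from [-5, +5]
    degrees; masks are transformed identically (nearest-neighbour).
    """
    rng = np.random.default_rng(seed)
    out: List[ImageRecord] = []
    for rec in records:
        out.append(rec)
        out.append(ImageRecord(image=rec.image[:, ::-1].copy(),
                               mask=rec.mask[:, ::-1].copy(),
                               id=rec.id + "_hflip", provenance="hflip"))
        out.append(ImageRecord(image=rec.image[::-1, :].copy(),
                               mask=rec.mask[::-1, :].copy(),
                               id=rec.id + "_vflip", provenance="vflip"))
        angle = rng.uniform(-5.0, 5.0)
        out.append(_rotate(rec, angle, rec.id + "_rot"))
    return out


def split(records: Sequence[ImageRecord], spec: SplitSpec = SplitSpec()):
    """Seeded shuffle then 6:2:2 partition (sizes floor/floor/remainder)."""
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    order = np.random.default_rng(spec.seed).permutation(n)
    n_train = int(spec.ratios[0] * n)
    n_val = int(spec.ratios[1] * n)
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    pick = lambda idx: [records[i] for i in idx]
    return pick(idx_train), pick(idx_val), pick(idx_test)


def split_grouped(records: Sequence[ImageRecord], spec: SplitSpec = SplitSpec()):
    """Leak-free variant: augment-siblings (shared id stem) stay together."""
    stems: List[str] = []
    by_stem: dict = {}
    for rec in records:
        stem = rec.id.rsplit("_", 1)[0] if rec.provenance != "original" else rec.id
        if stem not in by_stem:
            by_stem[stem] = []
            stems.append(stem)
        by_stem[stem].append(rec)
    if len(stems) < 3:
        raise ValueError("need at least 3 source groups to split")
    order = np.random.default_rng(spec.seed).permutation(len(stems))
    n_train = int(spec.ratios[0] * len(stems))
    n_val = int(spec.ratios[1] * len(stems))
    groups = [stems[i] for i in order]
    expand = lambda names: [r for s in names for r in by_stem[s]]
    return (expand(groups[:n_train]),
            expand(groups[n_train:n_train + n_val]),
            expand(groups[n_train + n_val:]))
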