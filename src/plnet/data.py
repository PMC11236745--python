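"""Folder-dataset loading, preprocessing and geometric augmentation.

Datasets live as ``images/`` and ``masks/`` subfolders with matching file
stems (PNG masks; images may be PNG/JPEG/TIFF).  Preprocessing resizes to a
square working resolution (bilinear for images, nearest-neighbor for masks so
labels survive exactly) and, for dermoscopy-style RGB input, optionally
applies gray-world color constancy.  Augmentation draws random rotations
(+-25 deg), shifts (+-15% per axis) and independent horizontal/vertical
flips, applying the identical geometric transform to image and mask.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "SegSample",
    "SplitSpec",
    "DatasetSplits",
    "gray_world",
    "preprocess",
    "augment",
    "load_dataset",
    "read_manifest",
    "write_manifest",
]

IMAGE_EXTS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


@dataclass
class SegSample:
    """An image/mask pair: image HxWxC float in [0,1], mask HxW int labels."""

    image: np.ndarray
    mask: np.ndarray
    id: str = ""
    class_names: tuple = ("background", "foreground")

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.ndim == 2:
            self.image = self.image[..., None]
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} vs mask {self.mask.shape}"
            )
        if self.mask.min() < 0 or self.mask.max() >= len(self.class_names):
            raise ValueError("mask labels exceed the class vocabulary")


@dataclass
class SplitSpec:
    """Train/val/test fractions plus the shuffling seed."""

    train: float = 0.6
    val: float = 0.2
    test: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.train, self.val, self.test) < 0:
            raise ValueError("split fractions must be non-negative")


@dataclass
class DatasetSplits:
    train: list = field(default_factory=list)
    val: list = field(default_factory=list)
    test: list = field(default_factory=list)
    errors: list = field(default_factory=list)


def gray_world(image):
    """Gray-world color constancy: scale each channel so the per-channel
    means all equal the global mean; result clipped to [0, 1].

    Single-channel input is returned unchanged with a warning (the correction
    is undefined there); a channel with zero mean passes through unscaled.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        warnings.warn("gray_world expects a 3-channel image; returning input")
        return image
    means = image.mean(axis=(0, 1))
    target = means.mean()
    scale = np.where(means > 0, target / np.where(means > 0, means, 1.0), 1.0)
    return np.clip(image * scale[None, None, :], 0.0, 1.0)


def preprocess(sample: SegSample, size=224) -> SegSample:
    """Resize to ``size`` x ``size`` (bilinear image / nearest mask) with
    intensities in [0, 1].  A sample already at the target size is returned
    with bit-identical arrays."""
    img, mask = sample.image, sample.mask
    if img.size == 0:
        raise ValueError("empty image")
    if img.max() > 1.0:
        img = img / 255.0
    if img.shape[:2] != (size, size):
        img = _sk_resize(
            img, (size, size), order=1, preserve_range=True, anti_aliasing=True
        )
        img = np.clip(img, 0.0, 1.0)
        mask = _sk_resize(
            mask.astype(np.float64),
            (size, size),
            order=0,
            preserve_range=True,
            anti_aliasing=False,
        ).astype(sample.mask.dtype)
    return SegSample(img, mask, id=sample.id, class_names=sample.class_names)


def _affine_matrix(h, w, angle_deg, shift_rc, flip_v, flip_h):
    """Forward homogeneous transform in (row, col) coordinates: flip about
    the center, rotate about the center, then translate."""
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    th = np.deg2rad(angle_deg)
    rot = np.array(
        [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
    )
    flip = np.diag([-1.0 if flip_v else 1.0, -1.0 if flip_h else 1.0, 1.0])
    to_c = np.array([[1, 0, -cy], [0, 1, -cx], [0, 0, 1.0]])
    from_c = np.array([[1, 0, cy], [0, 1, cx], [0, 0, 1.0]])
    shift = np.array([[1, 0, shift_rc[0]], [0, 1, shift_rc[1]], [0, 0, 1.0]])
    return shift @ from_c @ rot @ flip @ to_c


def _warp(arr, minv, order, mode, cval=0.0):
    return ndimage.affine_transform(
        arr, minv[:2, :2], offset=minv[:2, 2], order=order, mode=mode, cval=cval
    )


def augment(sample: SegSample, rng) -> SegSample:
    """Random rotation (uniform +-25 deg), shifts (uniform +-15% per axis)
    and independent 50% horizontal/vertical flips.

    Image channels are warped bilinearly with reflect padding, the mask with
    nearest-neighbor and constant-0 (background) padding; image and mask get
    the identical transform.  Deterministic for a fixed ``rng`` state.
    """
    h, w = sample.mask.shape
    angle = rng.uniform(-25.0, 25.0)
    shift = (rng.uniform(-0.15, 0.15) * h, rng.uniform(-0.15, 0.15) * w)
    flip_h = rng.random() < 0.5
    flip_v = rng.random() < 0.5
    minv = np.linalg.inv(_affine_matrix(h, w, angle, shift, flip_v, flip_h))
    img = np.stack(
        [
            _warp(sample.image[..., c], minv, order=1, mode="reflect")
            for c in range(sample.image.shape[2])
        ],
        axis=-1,
    )
    mask = _warp(
        sample.mask.astype(np.float64), minv, order=0, mode="constant", cval=0.0
    ).astype(sample.mask.dtype)
    return SegSample(
        np.clip(img, 0.0, 1.0), mask, id=sample.id, class_names=sample.class_names
    )


# ---------------------------------------------------------------------------
# folder datasets
# ---------------------------------------------------------------------------


def _load_image(path: Path):
    raw = np.asarray(iio.imread(path))
    arr = raw.astype(np.float64)
    if np.issubdtype(raw.dtype, np.integer):
        arr = arr / np.iinfo(raw.dtype).max
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    return arr


def _load_mask(path: Path):
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    vals = np.unique(arr)
    if set(vals.tolist()) <= {0, 255}:
        arr = (arr > 0).astype(np.int64)
    return arr.astype(np.int64)


def load_dataset(directory, split: SplitSpec, class_names=None) -> DatasetSplits:
    """Read an ``images/`` + ``masks/`` folder dataset and split it.

    Pairs are matched by filename stem (case-insensitive extension); images
    without masks are reported in ``errors`` and skipped.  Masks with values
    {0, 255} are binarized to {0, 1}.  The split is a seeded shuffle of the
    sorted ids, so membership is reproducible.
    """
    directory = Path(directory)
    img_dir, mask_dir = directory / "images", directory / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise FileNotFoundError(f"{directory} needs images/ and masks/")
    masks = {
        p.stem: p for p in mask_dir.iterdir() if p.suffix.lower() in IMAGE_EXTS
    }
    errors = []
    samples = []
    for p in sorted(img_dir.iterdir()):
        if p.suffix.lower() not in IMAGE_EXTS:
            continue
        mp = masks.pop(p.stem, None)
        if mp is None:
            errors.append(f"missing mask for {p.name}")
            continue
        img = _load_image(p)
        mask = _load_mask(mp)
        names = class_names or tuple(
            f"class{i}" for i in range(int(mask.max()) + 1)
        )
        if len(names) < mask.max() + 1:
            names = tuple(f"class{i}" for i in range(int(mask.max()) + 1))
        samples.append(SegSample(img, mask, id=p.stem, class_names=names))
    for stem in sorted(masks):
        errors.append(f"orphan mask {masks[stem].name}")

    ids = sorted(s.id for s in samples)
    rng = np.random.default_rng(split.seed)
    order = rng.permutation(len(ids))
    n = len(ids)
    n_train = int(round(split.train * n))
    n_val = int(round(split.val * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    by_id = {s.id: s for s in samples}
    shuffled = [by_id[ids[i]] for i in order]
    return DatasetSplits(
        train=shuffled[:n_train],
        val=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        errors=errors,
    )


def write_manifest(path, rows):
    """Write a CSV manifest of (id, image_path, mask_path[, split]) rows."""
    rows = list(rows)
    fields = ["id", "image_path", "mask_path"] + (
        ["split"] if rows and "split" in rows[0] else []
    )
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(rows)


def read_manifest(path):
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))
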