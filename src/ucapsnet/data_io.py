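"""Reading and preparing BUSI-style breast-ultrasound PNG datasets.

The expected directory layout is one folder per class::

    <root>/benign/<name>.png          # grayscale ultrasound image
    <root>/benign/<name>_mask.png     # binary lesion mask
    <root>/benign/<name>_mask_1.png   # optional extra masks, OR-combined
    <root>/malignant/...
    <root>/normal/...

Images are rescaled to [0,1]; masks are binarized.  Image resizing is
bilinear, mask resizing nearest-neighbor so masks stay exactly binary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize

log = logging.getLogger(__name__)

MASK_TOKEN = "_mask"


class Label(str, Enum):
    """Lesion class of a breast-ultrasound image."""

    NORMAL = "normal"
    BENIGN = "benign"
    MALIGNANT = "malignant"


CLASS_DIRS = (Label.BENIGN, Label.MALIGNANT, Label.NORMAL)


@dataclass
class LabeledImage:
    """One grayscale image with an optional binary lesion mask and a label.

    ``pixels`` is a 2-D float array in [0,1]; ``mask`` (if present) is a 2-D
    {0,1} array of the same shape.
    """

    pixels: np.ndarray
    mask: np.ndarray | None
    label: Label
    source_id: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError(f"{self.source_id}: pixels must be 2-D, got {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError(f"{self.source_id}: pixel values outside [0,1]")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.pixels.shape:
                raise ValueError(
                    f"{self.source_id}: mask shape {self.mask.shape} != image shape {self.pixels.shape}"
                )
            vals = np.unique(self.mask)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"{self.source_id}: mask must be binary")
            self.mask = self.mask.astype(np.uint8)
        self.label = Label(self.label)


@dataclass
class DatasetSplit:
    """A train/test partition, disjoint by ``source_id``."""

    train: list[LabeledImage]
    test: list[LabeledImage]
    seed: int = 0

    def __post_init__(self):
        tr = {r.source_id for r in self.train}
        te = {r.source_id for r in self.test}
        if tr & te:
            raise ValueError(f"train/test overlap: {sorted(tr & te)[:5]}")


def _read_gray(path: Path) -> np.ndarray:
    """Load a PNG as float grayscale in [0,1] (RGB collapsed by mean)."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise IOError(f"unreadable image file: {path}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    maxval = 65535.0 if arr.dtype == np.uint16 else 255.0
    return np.clip(arr.astype(np.float32) / maxval, 0.0, 1.0)


def _resize_image(img: np.ndarray, size: int) -> np.ndarray:
    out = resize(img, (size, size), order=1, anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _resize_mask(mask: np.ndarray, size: int) -> np.ndarray:
    out = resize(mask.astype(np.float32), (size, size), order=0,
                 anti_aliasing=False, preserve_range=True)
    return (out >= 0.5).astype(np.uint8)


def load_dataset(root_path: str | Path, image_size: int = 256) -> list[LabeledImage]:
    """Read a BUSI-layout directory into a list of :class:`LabeledImage`.

    Every non-mask PNG becomes one record; all mask files sharing its stem
    (``<stem>_mask*.png``) are OR-combined into a single binary mask.  A
    lesion-class image with no mask file yields a warning and a record with
    ``mask=None``.
    """
    root = Path(root_path)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {root}")
    if image_size < 32:
        raise ValueError("image_size must be >= 32")
    records: list[LabeledImage] = []
    for label in CLASS_DIRS:
        cdir = root / label.value
        if not cdir.is_dir():
            continue
        files = sorted(p for p in cdir.iterdir() if p.suffix.lower() == ".png")
        images = [p for p in files if MASK_TOKEN not in p.stem]
        masks = [p for p in files if MASK_TOKEN in p.stem]
        for img_path in images:
            stem = img_path.stem
            own = [m for m in masks if m.stem.split(MASK_TOKEN)[0] == stem]
            pixels = _resize_image(_read_gray(img_path), image_size)
            mask = None
            if own:
                union = np.zeros_like(_read_gray(own[0]), dtype=bool)
                for m in own:
                    union |= _read_gray(m) >= 0.5
                mask = _resize_mask(union.astype(np.uint8), image_size)
            elif label is not Label.NORMAL:
                warnings.warn(f"lesion image without mask: {img_path}", stacklevel=2)
            records.append(LabeledImage(pixels, mask, label, f"{label.value}/{stem}"))
    return records


def save_dataset(records: list[LabeledImage], root_path: str | Path) -> None:
    """Write records back out in the BUSI layout (8-bit grayscale PNGs)."""
    root = Path(root_path)
    for rec in records:
        cdir = root / rec.label.value
        cdir.mkdir(parents=True, exist_ok=True)
        stem = rec.source_id.split("/")[-1]
        Image.fromarray(np.round(rec.pixels * 255).astype(np.uint8)).save(cdir / f"{stem}.png")
        if rec.mask is not None:
            Image.fromarray((rec.mask * 255).astype(np.uint8)).save(cdir / f"{stem}_mask.png")


def shuffle_paired(images: list, labels: list, seed: int) -> tuple[list, list]:
    """Permute images and labels by one shared seeded permutation."""
    if len(images) != len(labels):
        raise ValueError(f"length mismatch: {len(images)} images vs {len(labels)} labels")
    perm = np.random.default_rng(seed).permutation(len(images))
    return [images[i] for i in perm], [labels[i] for i in perm]


def prepare_for_classifier(mask: np.ndarray, expected_size: int = 256) -> np.ndarray:
    """Convert a binary segmentation mask into the classifier's input.

    The mask is downsampled to half its side (nearest-neighbor, so values
    stay binary) and replicated into three identical channels, e.g.
    256×256 → 128×128×3.
    """
    mask = np.asarray(mask)
    if mask.shape != (expected_size, expected_size):
        raise ValueError(
            f"expected a {expected_size}x{expected_size} mask, got {mask.shape}"
        )
    small = _resize_mask(mask, expected_size // 2)
    return np.repeat(small[:, :, None], 3, axis=2).astype(np.float32)
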