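"""Seeded synthetic breast-ultrasound phantoms.

Each phantom is a square grayscale image with fully-developed multiplicative
speckle (unit-mean gamma noise) over an echogenic background.  Lesion-class
phantoms carry one hypoechoic (darker) lesion whose morphology depends on the
class:

* benign  — a smooth rotated ellipse (well-circumscribed margin),
* malignant — a spiculated region whose radius is modulated with angle,
  ``r(theta) = r0 * (1 + a * |sin(k * theta / 2)|)`` for ``k`` spicules,
* normal — no lesion; the ground-truth mask is all zeros.

The exact rasterized lesion interior is returned as the binary mask, so
segmentation quality can be scored against a perfect reference.  The
generator makes no attempt at physical wave simulation (no beamforming,
attenuation or posterior shadowing); it provides just the two properties the
two-stage pipeline needs to be learnable: hypoechoic lesions on speckle, and
margin irregularity that separates the classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import Label, LabeledImage


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and noise settings for phantom generation.

    ``lesion_radius_range`` is a fraction of the image side; with the default
    image side of 128 px the lesion radius spans roughly 15–36 px, similar in
    relative size to BUSI lesions.  ``speckle_shape`` is the gamma shape of
    the unit-mean multiplicative noise (contrast std/mean = 1/sqrt(shape)).
    """

    size: int = 128
    background_mean: float = 0.55
    lesion_intensity_drop: float = 0.45
    speckle_shape: float = 4.0
    benign_axis_ratio_range: tuple[float, float] = (0.65, 0.95)
    malignant_n_spicules: tuple[int, int] = (6, 12)
    malignant_spicule_amp: tuple[float, float] = (0.35, 0.7)
    lesion_radius_range: tuple[float, float] = (0.12, 0.28)
    seed: int = 0

    def __post_init__(self):
        if self.size < 32:
            raise ValueError("size must be >= 32")
        if not 0 < self.background_mean < 1:
            raise ValueError("background_mean must be in (0,1)")
        if not 0 < self.lesion_intensity_drop < 1:
            raise ValueError("lesion_intensity_drop must be in (0,1)")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be > 0")
        for name in ("benign_axis_ratio_range", "malignant_n_spicules",
                     "malignant_spicule_amp", "lesion_radius_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low > high")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("lesion_radius_range fractions must lie in (0, 0.5)")


def _lesion_mask(label: Label, cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    cy, cx = rng.uniform(0.35 * n, 0.65 * n, size=2)
    r0 = rng.uniform(*cfg.lesion_radius_range) * n
    rot = rng.uniform(0, np.pi)
    dy, dx = yy - cy, xx - cx
    # rotate into the lesion frame
    u = np.cos(rot) * dx + np.sin(rot) * dy
    v = -np.sin(rot) * dx + np.cos(rot) * dy
    if label is Label.BENIGN:
        ratio = rng.uniform(*cfg.benign_axis_ratio_range)
        return ((u / r0) ** 2 + (v / (r0 * ratio)) ** 2 <= 1.0).astype(np.uint8)
    k = rng.integers(cfg.malignant_n_spicules[0], cfg.malignant_n_spicules[1] + 1)
    amp = rng.uniform(*cfg.malignant_spicule_amp)
    theta = np.arctan2(v, u)
    r_theta = r0 * (1.0 + amp * np.abs(np.sin(k * theta / 2.0)))
    return (np.hypot(u, v) <= r_theta).astype(np.uint8)


def make_phantom(class_label: Label | str, config: PhantomConfig, seed: int) -> LabeledImage:
    """Generate one phantom of the given class, deterministic in ``seed``."""
    label = Label(class_label)
    rng = np.random.default_rng(seed)
    n = config.size
    if label is Label.NORMAL:
        mask = np.zeros((n, n), dtype=np.uint8)
    else:
        mask = _lesion_mask(label, config, rng)
    img = np.full((n, n), config.background_mean, dtype=np.float64)
    img[mask == 1] *= 1.0 - config.lesion_intensity_drop
    shape = config.speckle_shape
    img *= rng.gamma(shape, 1.0 / shape, size=(n, n))
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return LabeledImage(img, mask, label, f"{label.value}/phantom_{seed}")


def make_dataset(n_per_class: int, config: PhantomConfig) -> list[LabeledImage]:
    """Generate ``n_per_class`` phantoms per class, deterministic in ``config.seed``.

    Seeds for individual phantoms are drawn from a generator seeded with
    ``config.seed`` so the full dataset is reproducible.
    """
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    master = np.random.default_rng(config.seed)
    records: list[LabeledImage] = []
    for label in (Label.NORMAL, Label.BENIGN, Label.MALIGNANT):
        for i in range(n_per_class):
            sub = int(master.integers(0, 2**31 - 1))
            rec = make_phantom(label, config, sub)
            rec.source_id = f"{label.value}/phantom_{i:04d}"
            records.append(rec)
    return records


def irregularity_index(mask: np.ndarray) -> float:
    """Boundary irregularity ``perimeter**2 / (4*pi*area)``; 1 for a disk."""
    from skimage.measure import perimeter

    area = float(mask.sum())
    if area == 0:
        return 0.0
    p = perimeter(mask, neighborhood=8)
    return float(p * p / (4.0 * np.pi * area))
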