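"""Two-stage workflow orchestration.

Stage 1 trains the enhanced U-Net on image/mask pairs and predicts a binary
lesion mask for every lesion-class image; stage 2 converts those predicted
masks into 3-channel classifier inputs and trains the capsule network to
call each lesion benign or malignant.  A single master seed derives every
stage seed, so a rerun with the same seed reproduces the manifest exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import capsnet
from .capsnet import CapsConfig, build_capsnet, predict_class, train_classifier
from .data_io import LabeledImage, Label, load_dataset, prepare_for_classifier
from .metrics import EvalReport, classification_report, segmentation_report
from .seg_unet import (
    SegConfig,
    build_enhanced_unet,
    predict_masks,
    train_segmenter,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings for one training stage."""

    learning_rate: float
    epochs: int
    batch_size: int
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


# paper-scale defaults: 50 epochs, batch 25; lr 1e-5 (segmenter) / 5e-3 (classifier)
DEFAULT_TC_SEG = TrainConfig(learning_rate=1e-5, epochs=50, batch_size=25)
DEFAULT_TC_CLS = TrainConfig(learning_rate=5e-3, epochs=50, batch_size=25)


@dataclass
class RunManifest:
    """Resolved configuration, seeds, audit lists and metric summaries."""

    master_seed: int
    seg_config: dict
    caps_config: dict
    tc_seg: dict
    tc_cls: dict
    train_ids: list[str]
    test_ids: list[str]
    segmentation: dict
    classification: dict
    seg_history: list[dict] = field(default_factory=list)
    cls_history: list[dict] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _derive_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def run_two_stage(
    data: str | Path | list[LabeledImage],
    seg_config: SegConfig | None = None,
    caps_config: CapsConfig | None = None,
    tc_seg: TrainConfig | None = None,
    tc_cls: TrainConfig | None = None,
    seed: int = 0,
    test_fraction: float = 0.2,
    use_ground_truth_masks: bool = False,
    seg_dice_weight: float = 0.0,
    out_dir: str | Path | None = None,
) -> RunManifest:
    """Run segmentation → classification end to end and evaluate both stages.

    ``data`` is a BUSI-layout directory or an in-memory record list.  The
    records are split into stratified train/test sets; the segmenter trains
    on training image/mask pairs, then predicts masks for every lesion-class
    image; the classifier trains on the training lesions' predicted masks
    (ground-truth masks instead when ``use_ground_truth_masks``) and is
    scored on the held-out lesions.
    """
    seg_config = seg_config or SegConfig()
    caps_config = caps_config or CapsConfig()
    tc_seg = tc_seg or DEFAULT_TC_SEG
    tc_cls = tc_cls or DEFAULT_TC_CLS
    if caps_config.input_size != seg_config.input_size // 2:
        raise ValueError(
            "classifier input_size must be half the segmenter input_size "
            f"(got {caps_config.input_size} vs {seg_config.input_size})"
        )
    if isinstance(data, (str, Path)):
        records = load_dataset(data, image_size=seg_config.input_size)
    else:
        records = list(data)
    if not records:
        raise RuntimeError("stage: data loading — no records found")

    rng = np.random.default_rng(seed)
    seed_split, seed_seg_init, seed_seg_train, seed_cls_init, seed_cls_train = (
        _derive_seed(rng) for _ in range(5)
    )
    labels = [r.label.value for r in records]
    train_recs, test_recs = train_test_split(
        records, test_size=test_fraction, random_state=seed_split % 2**32,
        stratify=labels,
    )
    manifest = RunManifest(
        master_seed=seed,
        seg_config=dict(seg_config.__dict__),
        caps_config=dict(caps_config.__dict__),
        tc_seg=dict(tc_seg.__dict__), tc_cls=dict(tc_cls.__dict__),
        train_ids=sorted(r.source_id for r in train_recs),
        test_ids=sorted(r.source_id for r in test_recs),
        segmentation={}, classification={},
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    # ---- stage 1: segmentation ------------------------------------------
    try:
        seg_train = [r for r in train_recs if r.mask is not None]
        log.info("stage 1: training segmenter on %d records", len(seg_train))
        model_seg = build_enhanced_unet(seg_config, seed=seed_seg_init)
        tc1 = TrainConfig(tc_seg.learning_rate, tc_seg.epochs, tc_seg.batch_size,
                          seed=seed_seg_train)
        manifest.seg_history = train_segmenter(model_seg, seg_train, tc1,
                                               dice_weight=seg_dice_weight)
        # predict every mask once, batched; stage 2 reuses these
        predicted = dict(zip(
            (r.source_id for r in records),
            predict_masks(model_seg, [r.pixels for r in records]),
        ))
        seg_test = [r for r in test_recs if r.mask is not None]
        pairs = [(predicted[r.source_id], r.mask) for r in seg_test]
        manifest.segmentation = segmentation_report(pairs)
        log.info("stage 1 metrics: %s", manifest.segmentation)
    except Exception as exc:
        _finalize(manifest, out_dir)
        raise RuntimeError(f"stage 1 (segmentation) failed: {exc}") from exc

    # ---- stage 2: classification ----------------------------------------
    try:
        def to_input(rec: LabeledImage) -> np.ndarray:
            mask = rec.mask if use_ground_truth_masks else predicted[rec.source_id]
            return prepare_for_classifier(mask, expected_size=seg_config.input_size)

        lesion = (Label.BENIGN, Label.MALIGNANT)
        cls_train = [(to_input(r), r.label) for r in train_recs if r.label in lesion]
        cls_test = [(to_input(r), r.label) for r in test_recs if r.label in lesion]
        log.info("stage 2: training classifier on %d lesions", len(cls_train))
        model_cls = build_capsnet(caps_config, seed=seed_cls_init)
        tc2 = TrainConfig(tc_cls.learning_rate, tc_cls.epochs, tc_cls.batch_size,
                          seed=seed_cls_train)
        manifest.cls_history = train_classifier(model_cls, cls_train, tc2)
        truths = [lab for _, lab in cls_test]
        preds = [predict_class(model_cls, xi)[0] for xi, _ in cls_test]
        report = classification_report(truths, preds,
                                       classes=[l.value for l in lesion])
        manifest.classification = report.to_dict()
        log.info("stage 2 accuracy: %.3f", report.accuracy)
    except Exception as exc:
        _finalize(manifest, out_dir)
        raise RuntimeError(f"stage 2 (classification) failed: {exc}") from exc

    _finalize(manifest, out_dir)
    return manifest


def _finalize(manifest: RunManifest, out_dir) -> None:
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest.save(out / "manifest.json")


def kfold_cv(labels: list, k: int = 5, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold partition over class labels.

    Returns ``k`` (train_indices, test_indices) pairs; every sample lands in
    exactly one test fold and per-class fold sizes differ by at most one.
    """
    labels = [getattr(l, "value", l) for l in labels]
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(labels) < k:
        raise ValueError(f"need at least k={k} samples, got {len(labels)}")
    from collections import Counter

    for cls, n in Counter(labels).items():
        if n < k:
            raise ValueError(f"class {cls!r} has only {n} members (< k={k})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**32)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def cross_validate_classifier(
    data: list[tuple[np.ndarray, Label]],
    caps_config: CapsConfig | None = None,
    tc: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> EvalReport:
    """K-fold CV of the capsule classifier, pooling out-of-fold predictions."""
    caps_config = caps_config or CapsConfig()
    tc = tc or DEFAULT_TC_CLS
    labels = [Label(l) for _, l in data]
    folds = kfold_cv(labels, k=k, seed=seed)
    rng = np.random.default_rng(seed)
    truths: list[Label] = []
    preds: list[Label] = []
    for fold_no, (tr, te) in enumerate(folds, 1):
        log.info("fold %d/%d: %d train / %d test", fold_no, k, len(tr), len(te))
        model = build_capsnet(caps_config, seed=_derive_seed(rng))
        tc_fold = TrainConfig(tc.learning_rate, tc.epochs, tc.batch_size,
                              seed=_derive_seed(rng))
        train_classifier(model, [data[i] for i in tr], tc_fold)
        for i in te:
            truths.append(labels[i])
            preds.append(predict_class(model, data[i][0])[0])
    return classification_report(truths, preds,
                                 classes=[l.value for l in capsnet.CLASS_ORDER])
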