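"""Reproducible synthetic-recovery benchmarks.

Each function runs a fixed small-scale experiment on seeded phantoms and
returns its summary metrics.  These protocols are what the test suite and
the results-reproduction script execute; they are deliberately small enough
for a single CPU (tiny network configurations, tens of images) while still
exercising every stage of the pipeline.

All randomness — phantom generation, train/test partition, weight init,
batch order, dropout, augmentation — derives from the single ``seed``
argument.
"""

from __future__ import annotations

import numpy as np

from .capsnet import CapsConfig, build_capsnet, predict_class, train_classifier
from .data_io import Label, shuffle_paired
from .metrics import dice
from .pipeline import RunManifest, TrainConfig, run_two_stage
from .seg_unet import SegConfig, build_enhanced_unet, predict_mask, train_segmenter
from .synthetic_data import PhantomConfig, make_dataset

# tiny-run training settings: the paper-scale defaults (50 epochs, batch 25)
# target full-size training; these short recovery runs use a conventional
# small-model Adam rate and small batches so optimization converges within
# the few hundred steps the runs allow
SEG_TC = dict(learning_rate=3e-3, epochs=10, batch_size=5)
# soft-Dice weight added to BCE in the recovery runs: guards the short runs
# against the all-background local optimum of pure BCE on sparse foreground
SEG_DICE_WEIGHT = 0.5
CLS_TC = dict(learning_rate=5e-3, epochs=15, batch_size=5)

TINY_SEG = dict(input_size=64, base_filters=8, depth=3)
TINY_CAPS = dict(input_size=64, dense_layers=2, primary_caps_dim=4)


def _spawn(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(rng.integers(0, 2**31 - 1)) for _ in range(n)]


def segmentation_recovery(seed: int = 0, n_train: int = 50, n_test: int = 20,
                          n_runs: int = 3) -> dict:
    """Train the tiny U-Net on speckle phantoms and score held-out Dice.

    The phantom set is fixed by ``seed``; ``n_runs`` independent
    init/training seeds are used and the per-run mean test Dice values are
    summarized by their median.
    """
    data_seed, split_seed, *run_seeds = _spawn(seed, 2 + n_runs)
    recs = make_dataset((n_train + n_test) // 3 + 1, PhantomConfig(size=64, seed=data_seed))
    recs, _ = shuffle_paired(recs, [r.label for r in recs], seed=split_seed)
    train, test = recs[:n_train], recs[n_train : n_train + n_test]
    cfg = SegConfig(**TINY_SEG)
    dices = []
    for rs in run_seeds:
        model = build_enhanced_unet(cfg, seed=rs)
        train_segmenter(model, train, TrainConfig(**SEG_TC, seed=rs + 1),
                        dice_weight=SEG_DICE_WEIGHT)
        dices.append(float(np.mean([
            dice(predict_mask(model, r.pixels), r.mask) for r in test
        ])))
    return {"per_run_dice": dices, "median_dice": float(np.median(dices)),
            "n_train": n_train, "n_test": n_test}


def _balanced_mask_data(seed: int, n_train_per_class: int = 50,
                        n_test_per_class: int = 20):
    """Stratified benign/malignant mask images (3-channel) at 64 px."""
    data_seed, order_seed = _spawn(seed, 2)
    n = n_train_per_class + n_test_per_class
    recs = [r for r in make_dataset(n, PhantomConfig(size=64, seed=data_seed))
            if r.label is not Label.NORMAL]
    xs = [np.repeat(r.mask[:, :, None], 3, axis=2).astype(np.float32) for r in recs]
    ys = [r.label for r in recs]
    xs, ys = shuffle_paired(xs, ys, seed=order_seed)
    by_class = {Label.BENIGN: [], Label.MALIGNANT: []}
    for x, y in zip(xs, ys):
        by_class[y].append((x, y))
    train = (by_class[Label.BENIGN][:n_train_per_class]
             + by_class[Label.MALIGNANT][:n_train_per_class])
    test = (by_class[Label.BENIGN][n_train_per_class:n]
            + by_class[Label.MALIGNANT][n_train_per_class:n])
    return train, test


def classifier_recovery(seed: int = 0, n_runs: int = 3) -> dict:
    """Train the tiny capsule classifier on phantom lesion masks.

    100 balanced training masks, 40 held-out; ``n_runs`` training seeds with
    the median held-out accuracy as the summary.  A shuffled-label control
    (same protocol, labels permuted independently of the images) estimates
    the chance-level baseline.
    """
    exp_seed, null_seed, *run_seeds = _spawn(seed, 2 + n_runs)
    train, test = _balanced_mask_data(exp_seed)
    cfg = CapsConfig(**TINY_CAPS)

    def run(data, rs):
        model = build_capsnet(cfg, seed=rs)
        train_classifier(model, data, TrainConfig(**CLS_TC, seed=rs + 1))
        hits = sum(predict_class(model, x)[0] is y for x, y in test)
        return hits / len(test)

    accs = [run(train, rs) for rs in run_seeds]
    # control: same protocol with labels permuted independently of the
    # images, one permutation per run seed, summarized like the signal runs
    rng = np.random.default_rng(null_seed)
    labels = [y for _, y in train]
    null_accs = []
    for rs in run_seeds:
        null_train = [(x, labels[j]) for (x, _), j in
                      zip(train, rng.permutation(len(train)))]
        null_accs.append(run(null_train, rs))
    return {"per_run_accuracy": accs,
            "median_accuracy": float(np.median(accs)),
            "per_run_null_accuracy": null_accs,
            "null_control_accuracy": float(np.median(null_accs)),
            "n_train": len(train), "n_test": len(test)}


def end_to_end_recovery(seed: int = 0, n_per_class: int = 50) -> dict:
    """Full two-stage run on 3×``n_per_class`` phantoms.

    Phantoms are rendered at 128 px — the segmenter works at 128 and the
    classifier at the workflow's half-resolution 64, preserving the 2:1
    stage ratio of the full-size design.  Returns both stage metrics plus a
    determinism check: the run is repeated under the same master seed and
    the manifests' metric blocks compared.
    """
    data_seed, run_seed = _spawn(seed, 2)

    def once() -> RunManifest:
        recs = make_dataset(n_per_class, PhantomConfig(size=128, seed=data_seed))
        return run_two_stage(
            recs,
            seg_config=SegConfig(input_size=128, base_filters=8, depth=3),
            caps_config=CapsConfig(**TINY_CAPS),
            tc_seg=TrainConfig(learning_rate=SEG_TC["learning_rate"], epochs=8,
                               batch_size=SEG_TC["batch_size"]),
            tc_cls=TrainConfig(**CLS_TC),
            seg_dice_weight=SEG_DICE_WEIGHT,
            seed=run_seed,
        )

    first, second = once(), once()
    return {
        "segmentation": first.segmentation,
        "classification_accuracy": first.classification["accuracy"],
        "rerun_identical": (first.segmentation == second.segmentation
                            and first.classification == second.classification),
        "n_phantoms": 3 * n_per_class,
    }
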