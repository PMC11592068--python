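"""Dataset reading, paired shuffling and classifier-input preparation."""

import numpy as np
import pytest
from PIL import Image

from ucapsnet import (
    Label,
    LabeledImage,
    load_dataset,
    prepare_for_classifier,
    save_dataset,
    shuffle_paired,
)
from ucapsnet.data_io import DatasetSplit


def _write_png(path, arr):
    Image.fromarray(arr.astype(np.uint8)).save(path)


def make_busi_fixture(root, n_benign=2):
    """Hand-built two-image benign fixture with one mask each."""
    d = root / "benign"
    d.mkdir(parents=True)
    rng = np.random.default_rng(0)
    for i in range(n_benign):
        img = rng.integers(0, 256, size=(40, 40))
        mask = np.zeros((40, 40))
        mask[10:30, 10:30] = 255
        _write_png(d / f"case{i}.png", img)
        _write_png(d / f"case{i}_mask.png", mask)
    return root


class TestLoadDataset:
    def test_reads_images_with_masks(self, tmp_path):
        make_busi_fixture(tmp_path)
        recs = load_dataset(tmp_path, image_size=64)
        assert len(recs) == 2
        for r in recs:
            assert r.label is Label.BENIGN
            assert r.pixels.shape == (64, 64)
            assert r.mask.shape == (64, 64)
            assert set(np.unique(r.mask)) <= {0, 1}

    def test_empty_class_dirs_yield_empty_list(self, tmp_path):
        for c in ("benign", "malignant", "normal"):
            (tmp_path / c).mkdir()
        assert load_dataset(tmp_path, image_size=64) == []

    def test_multiple_masks_are_or_combined(self, tmp_path):
        d = tmp_path / "malignant"
        d.mkdir()
        _write_png(d / "x.png", np.full((32, 32), 100))
        left = np.zeros((32, 32)); left[:, :16] = 255
        right = np.zeros((32, 32)); right[:, 16:] = 255
        _write_png(d / "x_mask.png", left)
        _write_png(d / "x_mask_1.png", right)
        (rec,) = load_dataset(tmp_path, image_size=32)
        assert rec.mask.sum() == 32 * 32  # union covers everything

    def test_missing_directory_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nowhere"):
            load_dataset(tmp_path / "nowhere")

    def test_lesion_image_without_mask_warns(self, tmp_path):
        d = tmp_path / "benign"
        d.mkdir()
        _write_png(d / "lonely.png", np.full((32, 32), 50))
        with pytest.warns(UserWarning, match="without mask"):
            (rec,) = load_dataset(tmp_path, image_size=32)
        assert rec.mask is None

    def test_roundtrip_through_png(self, tmp_path, small_dataset_64):
        save_dataset(small_dataset_64, tmp_path)
        back = load_dataset(tmp_path, image_size=64)
        assert len(back) == len(small_dataset_64)
        orig = {r.source_id: r for r in small_dataset_64}
        for r in back:
            o = orig[r.source_id]
            assert np.abs(r.pixels - o.pixels).max() <= 1 / 255 + 1e-6
            np.testing.assert_array_equal(r.mask, o.mask)


class TestLabeledImage:
    def test_rejects_out_of_range_pixels(self):
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            LabeledImage(np.full((8, 8), 1.5), None, Label.NORMAL, "x")

    def test_rejects_mask_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            LabeledImage(np.zeros((8, 8)), np.zeros((4, 4)), Label.BENIGN, "x")

    def test_rejects_non_binary_mask(self):
        with pytest.raises(ValueError, match="binary"):
            LabeledImage(np.zeros((8, 8)), np.full((8, 8), 0.5), Label.BENIGN, "x")

    def test_split_disjointness_enforced(self):
        a = LabeledImage(np.zeros((8, 8)), None, Label.NORMAL, "a")
        with pytest.raises(ValueError, match="overlap"):
            DatasetSplit(train=[a], test=[a])


class TestShufflePaired:
    def test_short_lists_unchanged(self):
        assert shuffle_paired([], [], seed=0) == ([], [])
        assert shuffle_paired(["a"], [1], seed=0) == (["a"], [1])

    def test_pairing_preserved(self):
        imgs = [f"img{i}" for i in range(100)]
        labs = [f"lab{i}" for i in range(100)]
        si, sl = shuffle_paired(imgs, labs, seed=42)
        assert sorted(zip(si, sl)) == sorted(zip(imgs, labs))
        assert si != imgs  # a 100-element identity permutation is ~impossible

    def test_deterministic_given_seed(self):
        imgs, labs = list(range(50)), list("ab" * 25)
        assert shuffle_paired(imgs, labs, 7) == shuffle_paired(imgs, labs, 7)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            shuffle_paired([1, 2], [1], seed=0)


class TestPrepareForClassifier:
    def test_zeros_and_ones_preserved(self):
        for fill in (0, 1):
            out = prepare_for_classifier(np.full((256, 256), fill, dtype=np.uint8))
            assert out.shape == (128, 128, 3)
            assert np.all(out == fill)

    def test_centered_square_downsamples_exactly(self):
        mask = np.zeros((256, 256), dtype=np.uint8)
        mask[96:160, 96:160] = 1  # 64x64 centered square
        out = prepare_for_classifier(mask)
        expected = np.zeros((128, 128))
        expected[48:80, 48:80] = 1  # 32x32 centered square
        for c in range(3):
            np.testing.assert_array_equal(out[:, :, c], expected)

    def test_channels_identical_and_binary(self):
        rng = np.random.default_rng(3)
        mask = (rng.random((256, 256)) > 0.5).astype(np.uint8)
        out = prepare_for_classifier(mask)
        np.testing.assert_array_equal(out[:, :, 0], out[:, :, 1])
        np.testing.assert_array_equal(out[:, :, 0], out[:, :, 2])
        assert set(np.unique(out)) <= {0.0, 1.0}

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="256x256"):
            prepare_for_classifier(np.zeros((128, 128)))
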