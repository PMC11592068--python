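"""Capsule network model: printed architecture trace and model contracts."""

import numpy as np
import pytest

from ucapsnet import (
    CapsConfig,
    Label,
    TrainConfig,
    build_capsnet,
    build_stem,
    predict_class,
    train_classifier,
)


class TestStemTrace:
    """Shape/parameter trace of the padded stem at the 128-px default."""

    def test_first_pad_shape(self):
        assert build_stem(CapsConfig()).layer("stem_pad1").output_shape == (134, 134, 3)

    def test_stem_conv_parameters_and_shape(self):
        li = build_stem(CapsConfig()).layer("stem_conv")
        assert li.params == 9408
        assert li.output_shape == (64, 64, 64)

    def test_second_pad_and_downsample_shapes(self):
        spec = build_stem(CapsConfig())
        assert spec.layer("stem_pad2").output_shape == (66, 66, 64)
        assert spec.layer("stem_pool").output_shape == (32, 32, 64)


class TestDenseBlockTrace:
    def test_printed_parameter_counts(self):
        spec = build_capsnet(CapsConfig()).network_spec()
        assert spec.layer("dense1_conv1x1").params == 8192
        assert spec.layer("dense1_bn2").params == 512
        assert spec.layer("dense1_conv3x3").params == 36864

    def test_growth_arithmetic_to_192_channels(self):
        spec = build_capsnet(CapsConfig()).network_spec()
        assert spec.layer("dense4_concat").output_shape == (32, 32, 192)
        for i in range(4):
            assert spec.layer(f"dense{i+1}_concat").output_shape[-1] == 64 + (i + 1) * 32

    def test_channel_mismatch_rejected(self):
        model = build_capsnet(CapsConfig(input_size=64, dense_layers=2,
                                         primary_caps_dim=4))
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 32, 32, 3), dtype=np.float32))


class TestFullNetwork:
    def test_single_softmax_output_of_width_two(self):
        spec = build_capsnet(CapsConfig()).network_spec()
        softmaxes = [li for li in spec if li.kind == "softmax"]
        assert len(softmaxes) == 1
        assert softmaxes[0].output_shape == (2,)

    def test_total_parameters_reproducible(self):
        a = build_capsnet(CapsConfig(), seed=1).network_spec()
        b = build_capsnet(CapsConfig(), seed=2).network_spec()
        assert a.total_parameters == b.total_parameters

    def test_primary_capsule_count_default(self):
        cfg = CapsConfig()
        assert cfg.n_primary_capsules == 32 * 32 * 192 // 8 == 24576

    def test_margin_parameter_ordering_enforced(self):
        with pytest.raises(ValueError):
            CapsConfig(m_plus=0.1, m_minus=0.9)
        with pytest.raises(ValueError):
            CapsConfig(routing_iterations=0)


@pytest.fixture(scope="module")
def tiny_caps_model():
    cfg = CapsConfig(input_size=32, stem_filters=16, growth_rate=8,
                     dense_layers=2, primary_caps_dim=4)
    return build_capsnet(cfg, seed=0), cfg


class TestInference:
    def test_probabilities_sum_to_one(self, tiny_caps_model):
        model, cfg = tiny_caps_model
        rng = np.random.default_rng(0)
        for _ in range(3):
            label, p = predict_class(model, rng.random((32, 32, 3)))
            assert p.sum() == pytest.approx(1.0, abs=1e-6)
            assert label in (Label.BENIGN, Label.MALIGNANT)

    def test_argmax_consistency(self, tiny_caps_model):
        model, _ = tiny_caps_model
        rng = np.random.default_rng(1)
        from ucapsnet.capsnet import CLASS_ORDER

        for _ in range(5):
            label, p = predict_class(model, rng.random((32, 32, 3)))
            assert label is CLASS_ORDER[int(p.argmax())]

    def test_inference_deterministic(self, tiny_caps_model):
        model, _ = tiny_caps_model
        x = np.random.default_rng(2).random((32, 32, 3))
        l1, p1 = predict_class(model, x)
        l2, p2 = predict_class(model, x)
        assert l1 == l2
        np.testing.assert_array_equal(p1, p2)

    def test_shape_mismatch_rejected(self, tiny_caps_model):
        model, _ = tiny_caps_model
        with pytest.raises(ValueError, match="32x32x3"):
            predict_class(model, np.zeros((64, 64, 3)))


class TestTraining:
    def _tiny_data(self, n=12):
        from ucapsnet import PhantomConfig, make_phantom

        data = []
        for s in range(n):
            label = "benign" if s % 2 == 0 else "malignant"
            rec = make_phantom(label, PhantomConfig(size=32), seed=s)
            x = np.repeat(rec.mask[:, :, None], 3, axis=2).astype(np.float32)
            data.append((x, rec.label))
        return data

    def test_epoch1_loss_reproducible(self):
        cfg = CapsConfig(input_size=32, stem_filters=16, growth_rate=8,
                         dense_layers=2, primary_caps_dim=4)
        data = self._tiny_data()
        losses = []
        for _ in range(2):
            model = build_capsnet(cfg, seed=3)
            hist = train_classifier(model, data, TrainConfig(1e-3, 1, 6, seed=4))
            losses.append(hist[0]["loss"])
        assert losses[0] == losses[1]

    def test_normal_label_rejected(self):
        from ucapsnet import PhantomConfig, make_phantom

        cfg = CapsConfig(input_size=32, stem_filters=16, growth_rate=8,
                         dense_layers=2, primary_caps_dim=4)
        model = build_capsnet(cfg, seed=0)
        rec = make_phantom("normal", PhantomConfig(size=32), seed=0)
        x = np.repeat(rec.mask[:, :, None], 3, axis=2).astype(np.float32)
        with pytest.raises(ValueError, match="binary"):
            train_classifier(model, [(x, rec.label)], TrainConfig(1e-3, 1, 2))

    def test_empty_dataset_rejected(self):
        model = build_capsnet(CapsConfig(input_size=32, stem_filters=16,
                                         growth_rate=8, dense_layers=2,
                                         primary_caps_dim=4))
        with pytest.raises(ValueError, match="empty"):
            train_classifier(model, [], TrainConfig(1e-3, 1, 2))
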