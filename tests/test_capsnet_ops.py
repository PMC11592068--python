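"""Closed-form and oracle tests for the capsule primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ucapsnet.capsnet import (
    CapsConfig,
    CapsuleTensor,
    dynamic_routing,
    margin_loss,
    primary_capsules,
    softmax,
    squash,
)


class TestSquash:
    def test_zero_vector_maps_to_zero(self):
        out = squash(np.zeros(8), epsilon=1e-7)
        assert np.all(out == 0)

    def test_unit_norm_input(self):
        # closed form: scale = (1/2) * 1/(1+eps)
        s = np.array([1.0, 0.0, 0.0])
        out = squash(s, epsilon=1e-7)
        assert np.linalg.norm(out) == pytest.approx(0.5 * (1 / (1 + 1e-7)), abs=1e-12)

    def test_three_four_vector(self):
        # ||s|| = 5 -> scale = (25/26) / 5 applied to (3,4)
        out = squash(np.array([3.0, 4.0]), epsilon=1e-7)
        expected = (25 / 26) * np.array([0.6, 0.8])
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            squash(np.array([np.nan, 1.0]))

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=6),
           st.floats(0.1, 20))
    @settings(max_examples=100, deadline=None)
    def test_norm_bounded_and_direction_preserved(self, vec, scale):
        s = np.asarray(vec) * scale
        out = squash(s, epsilon=1e-7)
        r = np.linalg.norm(s)
        assert np.linalg.norm(out) < 1
        if r > 1e-6:
            cos = float(out @ s) / (np.linalg.norm(out) * r + 1e-300)
            assert cos == pytest.approx(1.0, abs=1e-9)

    def test_norm_strictly_increasing_in_input_norm(self):
        radii = np.linspace(0.1, 20, 50)
        norms = [np.linalg.norm(squash(np.array([r, 0.0]))) for r in radii]
        assert np.all(np.diff(norms) > 0)


class TestSoftmax:
    def test_constant_vector_is_uniform(self):
        for c in (-3.0, 0.0, 7.5):
            out = softmax(np.full(5, c))
            np.testing.assert_allclose(out, 0.2, atol=1e-12)

    def test_zero_ln2_case(self):
        out = softmax(np.array([0.0, math.log(2.0)]))
        np.testing.assert_allclose(out, [1 / 3, 2 / 3], atol=1e-12)

    def test_shift_invariance(self):
        x = np.array([0.3, -1.2, 4.0, 2.2])
        np.testing.assert_allclose(softmax(x), softmax(x + 123.4), atol=1e-12)

    def test_sums_to_one_and_positive(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 7)) * 30
        out = softmax(x, axis=-1)
        assert np.all(out > 0)
        np.testing.assert_allclose(out.sum(axis=-1), 1.0, atol=1e-12)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            softmax(np.array([]))


class TestMarginLoss:
    def test_confident_correct_is_zero(self):
        assert margin_loss(np.array([1.0, 0.0]), np.array([0.95, 0.05])) == 0.0

    def test_hand_computed_case(self):
        # true-class term (0.9-0.3)^2 plus 0.5*(0.8-0.1)^2
        loss = margin_loss(np.array([1.0, 0.0]), np.array([0.3, 0.8]),
                           m_plus=0.9, m_minus=0.1, lambda_down=0.5)
        assert loss == pytest.approx(0.605, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            margin_loss(np.array([1.0, 0.0]), np.array([0.5]))

    def test_monotone_in_predictions(self):
        """Loss never increases as the true-class score rises and never
        decreases as a false-class score rises (checked on a grid)."""
        y = np.array([1.0, 0.0])
        grid = np.linspace(0, 1, 21)
        for other in grid:
            losses = [margin_loss(y, np.array([t, other])) for t in grid]
            assert np.all(np.diff(losses) <= 1e-12)
            losses_f = [margin_loss(y, np.array([other, f])) for f in grid]
            assert np.all(np.diff(losses_f) >= -1e-12)

    def test_batch_mean(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        yh = np.array([[0.3, 0.8], [0.95, 0.05]])
        # sample 2: true class at 0.05 -> (0.9-0.05)^2; false at 0.95 -> 0.5*(0.85)^2
        expected = (0.605 + (0.9 - 0.05) ** 2 + 0.5 * (0.95 - 0.1) ** 2) / 2
        assert margin_loss(y, yh) == pytest.approx(expected, abs=1e-12)


def reference_routing(u, w, iterations, epsilon):
    """Straight-line scalar reference of routing by agreement.

    Implements the update equations with plain Python loops over capsule
    indices; deliberately shares no code with the vectorized implementation.
    """
    n = len(u)
    k = len(w[0])
    o = len(w[0][0])
    d = len(u[0])
    u_hat = [[[sum(w[i][j][p][q] * u[i][q] for q in range(d)) for p in range(o)]
              for j in range(k)] for i in range(n)]
    b = [[0.0] * k for _ in range(n)]
    c = None
    v = None
    for it in range(iterations):
        c = []
        for i in range(n):
            m = max(b[i])
            e = [math.exp(bi - m) for bi in b[i]]
            z = sum(e)
            c.append([ei / z for ei in e])
        s = [[sum(c[i][j] * u_hat[i][j][p] for i in range(n)) for p in range(o)]
             for j in range(k)]
        v = []
        for j in range(k):
            norm = math.sqrt(sum(x * x for x in s[j]))
            scale = norm**2 / (1 + norm**2) / (norm + epsilon)
            v.append([scale * x for x in s[j]])
        if it < iterations - 1:
            for i in range(n):
                for j in range(k):
                    b[i][j] += sum(u_hat[i][j][p] * v[j][p] for p in range(o))
    return v, c


class TestDynamicRouting:
    def test_coefficients_are_distributions(self):
        rng = np.random.default_rng(3)
        u = squash(rng.normal(size=(7, 4)))
        w = rng.normal(size=(7, 2, 6, 4)) * 0.5
        _, _, c = dynamic_routing(u, w, routing_iterations=3, return_all=True)
        assert np.all(c >= 0)
        np.testing.assert_allclose(c.sum(axis=-1), 1.0, atol=1e-9)

    def test_single_capsule_single_class(self):
        rng = np.random.default_rng(4)
        u = squash(rng.normal(size=(1, 4)))
        w = rng.normal(size=(1, 1, 6, 4))
        scores, v, c = dynamic_routing(u, w, routing_iterations=3, return_all=True)
        assert c[0, 0] == pytest.approx(1.0, abs=1e-12)
        u_hat = np.einsum("nkod,nd->nko", w, u)
        np.testing.assert_allclose(v, squash(u_hat[0], 1e-7), atol=1e-12)

    @pytest.mark.parametrize("n,k,o,d,iters", [(3, 2, 4, 3, 3), (5, 3, 6, 4, 4), (2, 2, 16, 8, 1)])
    def test_matches_scalar_reference(self, n, k, o, d, iters):
        rng = np.random.default_rng(n * 100 + k)
        u = squash(rng.normal(size=(n, d)))
        w = rng.normal(size=(n, k, o, d)) * 0.7
        scores, v, c = dynamic_routing(u, w, routing_iterations=iters,
                                       epsilon=1e-7, return_all=True)
        v_ref, c_ref = reference_routing(u.tolist(), w.tolist(), iters, 1e-7)
        np.testing.assert_allclose(v, np.array(v_ref), atol=1e-9)
        np.testing.assert_allclose(c, np.array(c_ref), atol=1e-9)
        np.testing.assert_allclose(scores, np.linalg.norm(np.array(v_ref), axis=-1),
                                   atol=1e-9)

    def test_iteration_count_validated(self):
        with pytest.raises(ValueError):
            dynamic_routing(np.zeros((2, 4)), np.zeros((2, 2, 6, 4)),
                            routing_iterations=0)


class TestPrimaryCapsules:
    def test_capsule_count_from_feature_volume(self):
        cfg = CapsConfig()
        feats = np.zeros((32, 32, 192))
        caps = primary_capsules(feats, cfg)
        assert caps.values.shape == (32 * 32 * 192 // 8, 8)
        assert caps.values.shape[0] == 24576

    def test_norms_below_one(self):
        cfg = CapsConfig(input_size=64, dense_layers=2, primary_caps_dim=4)
        rng = np.random.default_rng(0)
        caps = primary_capsules(rng.normal(size=(4, 4, 16)) * 5, cfg)
        assert np.all(caps.norms < 1)

    def test_zero_features_zero_capsules(self):
        cfg = CapsConfig(input_size=64, dense_layers=2, primary_caps_dim=4)
        caps = primary_capsules(np.zeros((4, 4, 16)), cfg)
        assert np.all(caps.values == 0)

    def test_indivisible_volume_rejected(self):
        cfg = CapsConfig(input_size=64, dense_layers=2, primary_caps_dim=4)
        with pytest.raises(ValueError, match="divisible"):
            primary_capsules(np.zeros((3, 3, 5)), cfg)
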