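"""SGC encoding, SRM gating, fusion, loss, and end-to-end gradients."""

import numpy as np
import pytest

from sgcsrm import autodiff as ad
from sgcsrm.autodiff import Adam, Tensor
from sgcsrm.graph import normalize_adjacency
from sgcsrm.model import (
    ConvStackConfig,
    ModelConfig,
    SgcSrmModel,
    classify,
    composite_loss,
    conv_channels_for,
    fuse_bands,
    normalize_adjacency_t,
    reshape_to_grid,
    sgc_band_encode,
    srm_recalibrate,
    srm_style_integrate,
    srm_style_pool,
)
from sgcsrm.synthetic import SyntheticSpec, generate_de_dataset, resolve_layout

from _gradcheck import assert_gradients_match

rng = np.random.default_rng(7)


def tiny_model(layout, **overrides):
    kwargs = dict(
        n_channels=4,
        window_dim=6,
        bands=("alpha", "beta"),
        h1=5,
        seed=3,
        dtype="float64",
        conv=ConvStackConfig(3, 4, 2),
    )
    kwargs.update(overrides)
    return SgcSrmModel(ModelConfig(**kwargs), layout)


class TestSgcEncoder:
    def test_identity_graph_passthrough(self):
        # A = 0 => S = I; identity-like weights; nonnegative input passes relu
        x = Tensor(np.abs(rng.normal(size=(3, 4, 64))))
        a = Tensor(np.zeros((4, 4)))
        eye = Tensor(np.eye(64))
        out = sgc_band_encode(x, a, eye, eye)
        np.testing.assert_allclose(out.data, x.data, atol=1e-12)

    def test_matches_explicit_matrix_oracle(self):
        c, d, h1 = 4, 6, 5
        x = rng.normal(size=(3, c, d))
        a = rng.normal(size=(c, c))
        th1 = rng.normal(size=(d, h1))
        th2 = rng.normal(size=(h1, 64))
        out = sgc_band_encode(Tensor(x), Tensor(a), Tensor(th1), Tensor(th2)).data
        s = normalize_adjacency(a).values
        for n in range(3):
            expected = np.maximum(s @ (s @ x[n] @ th1) @ th2, 0.0)
            np.testing.assert_allclose(out[n], expected, atol=1e-6)

    def test_normalize_adjacency_t_matches_numpy_version(self):
        a = rng.normal(size=(5, 5))
        np.testing.assert_allclose(
            normalize_adjacency_t(Tensor(a)).data, normalize_adjacency(a).values, atol=1e-12
        )

    def test_permutation_equivariance(self):
        c, d = 5, 6
        x = rng.normal(size=(2, c, d))
        a = rng.normal(size=(c, c))
        th1 = rng.normal(size=(d, 7))
        th2 = rng.normal(size=(7, 64))
        perm = rng.permutation(c)
        p = np.eye(c)[perm]
        out = sgc_band_encode(Tensor(x), Tensor(a), Tensor(th1), Tensor(th2)).data
        out_p = sgc_band_encode(
            Tensor(x[:, perm]), Tensor(p @ a @ p.T), Tensor(th1), Tensor(th2)
        ).data
        np.testing.assert_allclose(out_p, out[:, perm], atol=1e-10)


class TestGridAndSrm:
    def test_reshape_row_major_and_inverse(self):
        vec = np.arange(64.0)[None, None, :]
        grid = reshape_to_grid(Tensor(vec)).data
        for r in range(8):
            for c in range(8):
                assert grid[0, 0, r, c] == 8 * r + c
        flat = grid.reshape(1, 1, 64)
        np.testing.assert_array_equal(flat, vec)
        big = reshape_to_grid(Tensor(np.zeros((5, 62, 64))))
        assert big.shape == (5, 62, 8, 8)
        with pytest.raises(ValueError, match="64"):
            reshape_to_grid(Tensor(np.zeros((1, 2, 63))))

    def test_style_pool_constant_and_hand_case(self):
        const = np.full((2, 3, 4, 4), 2.5)
        style = srm_style_pool(Tensor(const)).data
        np.testing.assert_allclose(style[..., 0], 2.5)
        assert np.all(style[..., 1] < 0.01)  # ~0 up to the eps guard
        quad = np.array([[[[1.0, 1.0], [3.0, 3.0]]]])
        style = srm_style_pool(Tensor(quad)).data
        assert style[0, 0, 0] == pytest.approx(2.0)
        assert style[0, 0, 1] == pytest.approx(1.0, abs=1e-4)

    def test_style_pool_matches_two_pass_moments(self):
        x = rng.normal(size=(4, 6, 7, 7))
        style = srm_style_pool(Tensor(x)).data
        np.testing.assert_allclose(style[..., 0], x.mean(axis=(2, 3)), atol=1e-6)
        np.testing.assert_allclose(style[..., 1], x.std(axis=(2, 3)), atol=1e-2)

    def test_zero_weights_give_half_gates(self):
        style = Tensor(rng.normal(size=(5, 3, 2)))
        gates = srm_style_integrate(
            style, Tensor(np.zeros((3, 2))), Tensor(np.ones(3)), Tensor(np.zeros(3)),
            np.zeros(3), np.ones(3), training=False,
        )
        np.testing.assert_allclose(gates.data, 0.5, atol=1e-12)

    def test_gate_limits_and_monotonicity(self):
        w = Tensor(np.array([[1.0, 0.0]]))
        gamma, beta = Tensor(np.ones(1)), Tensor(np.zeros(1))
        rm, rv = np.zeros(1), np.ones(1)

        def gate(mean_val):
            style = Tensor(np.array([[[mean_val, 0.0]]]))
            return srm_style_integrate(
                style, w, gamma, beta, rm, rv, training=False
            ).data.item()

        assert gate(60.0) > 1 - 1e-9
        assert gate(-60.0) < 1e-9
        values = [gate(z) for z in np.linspace(-5, 5, 21)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_gates_open_interval_on_random_inputs(self):
        x = Tensor(rng.normal(size=(1000, 4, 2)) * 10)
        w = Tensor(rng.normal(size=(4, 2)))
        gates = srm_style_integrate(
            x, w, Tensor(np.ones(4)), Tensor(np.zeros(4)), np.zeros(4), np.ones(4), False
        ).data
        assert np.all(gates > 0) and np.all(gates < 1)

    def test_recalibration_is_exact_elementwise_scaling(self):
        x = rng.normal(size=(3, 4, 5, 5))
        gates = rng.uniform(0.05, 0.95, size=(3, 4))
        out = srm_recalibrate(Tensor(x), Tensor(gates)).data
        np.testing.assert_allclose(out, x * gates[:, :, None, None], atol=1e-15)
        assert np.all(np.abs(out) <= np.abs(x) + 1e-15)
        np.testing.assert_array_equal(
            srm_recalibrate(Tensor(x), Tensor(np.ones((3, 4)))).data, x
        )
        with pytest.raises(ValueError, match="gate shape"):
            srm_recalibrate(Tensor(x), Tensor(np.ones((3, 5))))


class TestConvStackShapes:
    @pytest.mark.parametrize(
        "n_channels,out1,out2,out3",
        [(62, 128, 256, 8), (12, 32, 64, 8)],
    )
    def test_published_shape_column(self, n_channels, out1, out2, out3):
        cfg = conv_channels_for(n_channels)
        assert (cfg.out1, cfg.out2, cfg.out3) == (out1, out2, out3)
        layout = resolve_layout(SyntheticSpec(n_channels=n_channels))
        model = SgcSrmModel(
            ModelConfig(
                n_channels=n_channels, window_dim=4, bands=("alpha",), h1=8, seed=0
            ),
            layout,
        )
        enc = model.encoders[0]
        x = Tensor(np.random.default_rng(0).normal(size=(2, n_channels, 8, 8)).astype(np.float32))
        h = enc.conv1(x)
        assert h.shape == (2, out1, 7, 7)
        h = enc.srm1(h, training=True)
        assert h.shape == (2, out1, 7, 7)
        h = enc.conv2(h)
        assert h.shape == (2, out2, 6, 6)
        h = enc.conv3(enc.srm2(h, training=True))
        assert h.shape == (2, out3, 6, 6)
        pooled = ad.maxpool2d_2x2(h)
        assert pooled.shape == (2, out3, 3, 3)
        assert enc.out_dim == out3 * 9
        if out3 == 8:
            assert enc.out_dim == 72

    def test_srm_off_equals_plain_conv_stack(self, tiny_layout):
        model = tiny_model(tiny_layout, use_srm=False)
        enc = model.encoders[0]
        x = Tensor(rng.normal(size=(3, 4, 6)))
        out = enc(x, training=False).data
        h = sgc_band_encode(x, enc.adjacency, enc.theta1, enc.theta2)
        manual = ad.maxpool2d_2x2(enc.conv3(enc.conv2(enc.conv1(reshape_to_grid(h)))))
        np.testing.assert_allclose(out, manual.data.reshape(3, -1), atol=1e-12)


class TestFusionAndHead:
    def test_equal_logits_average(self):
        vecs = [Tensor(rng.normal(size=(4, 6))) for _ in range(4)]
        fused = fuse_bands(vecs, Tensor(np.zeros(4))).data
        np.testing.assert_allclose(
            fused, np.mean([v.data for v in vecs], axis=0), atol=1e-12
        )

    def test_dominant_logit_selects_band(self):
        vecs = [Tensor(rng.normal(size=(2, 3))) for _ in range(3)]
        logits = Tensor(np.array([0.0, 500.0, 0.0]))
        np.testing.assert_allclose(fuse_bands(vecs, logits).data, vecs[1].data, atol=1e-9)

    def test_weights_on_simplex(self):
        logits = Tensor(rng.normal(size=5))
        w = ad.softmax(logits).data
        assert w.sum() == pytest.approx(1.0, abs=1e-7)
        assert (w > 0).all()
        with pytest.raises(ValueError, match="fusion logits"):
            fuse_bands([Tensor(np.zeros((2, 3)))] * 2, Tensor(np.zeros(3)))

    def test_classifier_uniform_and_shift_invariant(self):
        fused = Tensor(rng.normal(size=(6, 8)))
        probs = classify(fused, Tensor(np.zeros((8, 3))), Tensor(np.zeros(3))).data
        np.testing.assert_allclose(probs, 1 / 3, atol=1e-12)
        w, b = Tensor(rng.normal(size=(8, 3))), Tensor(rng.normal(size=3))
        p1 = classify(fused, w, b).data
        p2 = classify(fused, w, b + 42.0).data
        np.testing.assert_allclose(p1, p2, atol=1e-9)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-7)


class TestCompositeLoss:
    def test_perfect_prediction_zero_loss(self):
        probs = np.eye(3)[np.array([0, 1, 2, 1])]
        probs = np.clip(probs, 1e-300, 1.0)
        lv = composite_loss(probs, np.array([0, 1, 2, 1]), [], 0.0)
        assert lv.total == pytest.approx(0.0, abs=1e-12)

    def test_uniform_predictor_ln3(self):
        probs = np.full((5, 3), 1 / 3)
        lv = composite_loss(probs, np.array([0, 1, 2, 0, 1]), [], 0.0)
        assert lv.total == pytest.approx(np.log(3.0), abs=1e-12)

    def test_hand_arithmetic_with_l1(self):
        probs = np.full((3, 3), 1 / 3)
        lv = composite_loss(probs, np.array([0, 1, 2]), [np.ones((2, 2))], 0.01)
        assert lv.l1 == pytest.approx(4.0)
        assert lv.total == pytest.approx(np.log(3.0) + 0.04, abs=1e-12)
        assert lv.total == lv.cross_entropy + 0.01 * lv.l1

    def test_label_out_of_range(self):
        with pytest.raises(ValueError, match="label"):
            composite_loss(np.full((1, 3), 1 / 3), np.array([5]), [], 0.0)


class TestAdjacencyDynamics:
    def test_freeze_keeps_adjacency_bit_identical(self, tiny_layout, small_dataset):
        model = tiny_model(tiny_layout, freeze_adjacency=True)
        before = [enc.adjacency.data.copy() for enc in model.encoders]
        x = rng.normal(size=(8, 4, 2, 6))
        y = np.array([0, 1, 2, 0, 1, 2, 0, 1])
        opt = Adam(model.parameters(), lr=0.05)
        for _ in range(3):
            opt.zero_grad()
            total, _ = model.loss(x, y, training=True)
            total.backward()
            opt.step()
        for a0, enc in zip(before, model.encoders):
            np.testing.assert_array_equal(a0, enc.adjacency.data)

    def test_l1_shrinks_adjacency_under_plain_gradient(self):
        # pure L1 objective (head detached): |A| decreases monotonically
        a = Tensor(rng.normal(size=(4, 4)), requires_grad=True)
        lr = 0.01
        prev = np.abs(a.data).sum()
        for _ in range(5):
            a.grad = None
            loss = a.abs().sum()
            loss.backward()
            a.data -= lr * a.grad
            now = np.abs(a.data).sum()
            assert now < prev
            prev = now

    def test_adjacency_moves_when_trainable(self, tiny_layout):
        model = tiny_model(tiny_layout)
        before = model.encoders[0].adjacency.data.copy()
        x = rng.normal(size=(8, 4, 2, 6))
        y = np.array([0, 1, 2, 0, 1, 2, 0, 1])
        opt = Adam(model.parameters(), lr=0.01)
        opt.zero_grad()
        total, _ = model.loss(x, y, training=True)
        total.backward()
        opt.step()
        assert not np.array_equal(before, model.encoders[0].adjacency.data)


class TestEndToEnd:
    def test_forward_determinism(self, tiny_layout):
        x = rng.normal(size=(5, 4, 2, 6))
        logits1 = tiny_model(tiny_layout).forward(x, training=False).data
        logits2 = tiny_model(tiny_layout).forward(x, training=False).data
        np.testing.assert_array_equal(logits1, logits2)

    def test_ablation_switch_consistency(self, tiny_layout):
        # -global: initial adjacency has no -1 entries
        with_g = tiny_model(tiny_layout, use_global=True)
        without_g = tiny_model(tiny_layout, use_global=False)
        assert without_g.applied_global_pairs == []
        assert (without_g._a_init >= 0).all()

    def test_parameter_count_is_config_function(self, tiny_layout):
        m1, m2 = tiny_model(tiny_layout), tiny_model(tiny_layout, seed=99)
        assert m1.parameter_count() == m2.parameter_count()
        spec62 = SyntheticSpec(n_channels=62)
        spec12 = SyntheticSpec(n_channels=12)
        big = SgcSrmModel(
            ModelConfig(n_channels=62, window_dim=4, bands=("alpha",), h1=8),
            resolve_layout(spec62),
        )
        small = SgcSrmModel(
            ModelConfig(n_channels=12, window_dim=4, bands=("alpha",), h1=8),
            resolve_layout(spec12),
        )
        assert big.parameter_count() > small.parameter_count()

    def test_loss_decomposition_exact(self, tiny_layout):
        model = tiny_model(tiny_layout, l1_strength=0.01)
        x = rng.normal(size=(6, 4, 2, 6))
        y = np.array([0, 1, 2, 0, 1, 2])
        total, lv = model.loss(x, y, training=False)
        assert lv.total == lv.cross_entropy + 0.01 * lv.l1
        assert float(total.data) == lv.total

    def test_end_to_end_gradients_match_finite_differences(self, tiny_layout):
        model = tiny_model(tiny_layout)
        x = rng.normal(size=(8, 4, 2, 6))
        y = np.array([0, 1, 2, 0, 1, 2, 0, 1])

        def build_loss():
            total, _ = model.loss(x, y, training=False)
            return total

        enc0 = model.encoders[0]
        params = {
            "theta1": enc0.theta1,
            "theta2": enc0.theta2,
            "A_0": enc0.adjacency,
            "A_1": model.encoders[1].adjacency,
            "srm_weights": enc0.srm1.weights,
            "fusion_logits": model.fusion_logits,
            "head_weight": model.head_weight,
        }
        assert_gradients_match(build_loss, params, rtol=1e-4)
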