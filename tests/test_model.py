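import numpy as np
import pytest

from skipgru import SkipGRUConfig, predict, train
from skipgru.model import (
    GRUParams,
    HeadParams,
    SkipGRUModel,
    SkipNetworkParams,
    clip_gradients,
    forward,
    forward_batch,
    gate_importance,
    global_norm,
    gru_cell,
    init_model,
    jump_probability,
    loss_and_grads,
)

from conftest import planted_dataset


class TestInit:
    def test_same_seed_bit_identical(self, tiny_config):
        a = init_model(5, 2, tiny_config, seed=4)
        b = init_model(5, 2, tiny_config, seed=4)
        for k, v in a.params().items():
            np.testing.assert_array_equal(v, b.params()[k])

    def test_shapes_follow_scalar_timestep_convention(self):
        cfg = SkipGRUConfig(hidden_size=16)
        m = init_model(5, 3, cfg, seed=0)
        assert m.gru.W_r.shape == (16, 17)  # [h_prev, scalar x_t]
        assert m.gru.W.shape == (16, 17)
        assert m.skip.W1.shape == (16, 1 + 16 + 5)  # [x; h_prev; onehot(t)]
        assert m.head.W.shape == (3, 16)  # three-class head

    def test_invalid_dims_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            init_model(0, 2, tiny_config)
        with pytest.raises(ValueError):
            init_model(3, 1, tiny_config)


class TestJumpGate:
    def test_keep_and_skip_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        skip = SkipNetworkParams(
            W1=rng.standard_normal((3, 3)), b1=rng.standard_normal(3),
            W2=rng.standard_normal((2, 3)), b2=rng.standard_normal(2),
        )
        pi = jump_probability(0.7, rng.standard_normal(2), skip)
        assert 0.0 < pi < 1.0

    def test_zero_output_layer_gives_exactly_half(self):
        skip = SkipNetworkParams(
            W1=np.ones((2, 3)), b1=np.zeros(2),
            W2=np.zeros((2, 2)), b2=np.zeros(2),
        )
        assert jump_probability(0.3, np.array([0.1, 0.2]), skip) == 0.5

    def test_matches_pencil_and_paper_evaluation(self):
        # gate input [x; h] = [0.5; 0.25], hand-set 2x2 weights
        skip = SkipNetworkParams(
            W1=np.array([[1.0, 2.0], [-1.0, 0.5]]), b1=np.array([0.1, -0.2]),
            W2=np.array([[1.0, -1.0], [0.5, 2.0]]), b2=np.array([0.0, 0.3]),
        )
        x, h = 0.5, np.array([0.25])
        s0 = max(1.0 * x + 2.0 * h[0] + 0.1, 0.0)          # 1.1
        s1 = max(-1.0 * x + 0.5 * h[0] - 0.2, 0.0)          # 0 (ReLU)
        l0 = 1.0 * s0 - 1.0 * s1                            # 1.1
        l1 = 0.5 * s0 + 2.0 * s1 + 0.3                      # 0.85
        expected = np.exp(l0) / (np.exp(l0) + np.exp(l1))
        assert jump_probability(x, h, skip) == pytest.approx(expected, abs=1e-12)


class TestGRUCell:
    def test_symmetric_zero_case(self):
        H = 3
        gru = GRUParams(
            W_r=np.zeros((H, H + 1)), b_r=np.zeros(H),
            W_z=np.zeros((H, H + 1)), b_z=np.zeros(H),
            W=np.zeros((H, H + 1)), b=np.zeros(H),
        )
        h = gru_cell(0.9, np.zeros(H), gru)
        np.testing.assert_array_equal(h, np.zeros(H))

    def test_hidden_state_stays_bounded(self):
        rng = np.random.default_rng(1)
        H = 4
        gru = GRUParams(
            W_r=rng.standard_normal((H, H + 1)) * 3, b_r=rng.standard_normal(H),
            W_z=rng.standard_normal((H, H + 1)) * 3, b_z=rng.standard_normal(H),
            W=rng.standard_normal((H, H + 1)) * 3, b=rng.standard_normal(H),
        )
        h = rng.uniform(-1, 1, H)
        for _ in range(50):
            h = gru_cell(rng.random(), h, gru)
            assert np.max(np.abs(h)) <= 1.0

    def test_matches_pencil_and_paper_evaluation(self):
        # 1-unit cell, hand-set scalar weights over [h_prev, x]
        gru = GRUParams(
            W_r=np.array([[0.5, -1.0]]), b_r=np.array([0.1]),
            W_z=np.array([[2.0, 0.5]]), b_z=np.array([-0.3]),
            W=np.array([[1.5, 1.0]]), b=np.array([0.2]),
        )
        h_prev, x = 0.4, 0.6

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        r = sig(0.5 * h_prev - 1.0 * x + 0.1)
        z = sig(2.0 * h_prev + 0.5 * x - 0.3)
        cand = np.tanh(1.5 * (r * h_prev) + 1.0 * x + 0.2)
        expected = (1 - z) * h_prev + z * cand
        got = gru_cell(x, np.array([h_prev]), gru)
        assert got[0] == pytest.approx(expected, abs=1e-12)


def _forced_gate_model(pi_high: bool, T=4, H=3, C=2, seed=0):
    """Model whose gate emits pi ~= 1.0 (or exactly representable 0-ish)."""
    m = init_model(T, C, SkipGRUConfig(hidden_size=H, gate_hidden=2, dropout=0.0),
                   seed=seed)
    m.skip.W1[:] = 0.0
    m.skip.b1[:] = 0.0
    m.skip.W2[:] = 0.0
    m.skip.b2[:] = (0.0, -60.0) if pi_high else (-60.0, 0.0)
    return m


class TestForward:
    def test_all_skipped_prediction_is_head_of_initial_state(self):
        m = _forced_gate_model(pi_high=False)
        row = np.random.default_rng(2).random(4)
        trace = forward(row, m, mode="hard")
        assert trace.skipped.all()
        np.testing.assert_array_equal(trace.hidden[-1], np.zeros(3))
        from skipgru.model import _softmax
        np.testing.assert_allclose(trace.class_probabilities, _softmax(m.head.b))

    def test_hard_equals_soft_at_extreme_gate(self):
        rng = np.random.default_rng(3)
        for pi_high in (True, False):
            m = _forced_gate_model(pi_high)
            row = rng.random(4)
            hard = forward(row, m, mode="hard")
            soft = forward(row, m, mode="soft")
            np.testing.assert_allclose(hard.hidden, soft.hidden, atol=1e-20)
            np.testing.assert_allclose(
                hard.class_probabilities, soft.class_probabilities, atol=1e-20
            )

    def test_hard_skip_is_bit_identical_carry_over(self):
        rng = np.random.default_rng(4)
        m = init_model(6, 2, SkipGRUConfig(hidden_size=5, dropout=0.0), seed=9)
        rows = rng.random((200, 6))
        for row in rows[:20]:
            trace = forward(row, m, mode="hard")
            h_prev = np.zeros(5)
            for t in range(6):
                if trace.skipped[t]:
                    assert np.array_equal(trace.hidden[t], h_prev)
                h_prev = trace.hidden[t]

    def test_class_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        m = init_model(5, 3, SkipGRUConfig(hidden_size=6, dropout=0.0), seed=1)
        probs, _ = forward_batch(m, rng.random((1000, 5)), mode="hard")
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_length_mismatch_and_nonfinite_rejected(self):
        m = init_model(4, 2, SkipGRUConfig(hidden_size=3), seed=0)
        with pytest.raises(ValueError):
            forward(np.ones(3), m)
        with pytest.raises(ValueError):
            forward_batch(m, np.array([[np.inf, 1, 1, 1]]))


class TestClipGradients:
    def test_three_four_vector_scaled_to_unit_norm(self):
        grads = {"w": np.array([3.0, 4.0])}
        clipped, scale = clip_gradients(grads, 1.0)
        np.testing.assert_allclose(clipped["w"], [0.6, 0.8])
        assert scale == pytest.approx(0.2)

    def test_small_gradient_unchanged(self):
        grads = {"w": np.array([0.3, 0.4])}
        clipped, scale = clip_gradients(grads, 1.0)
        assert scale == 1.0
        np.testing.assert_array_equal(clipped["w"], grads["w"])

    def test_direction_preserved(self):
        rng = np.random.default_rng(6)
        g = {"a": rng.standard_normal(20) * 10, "b": rng.standard_normal((3, 4)) * 10}
        clipped, _ = clip_gradients(g, 1.0)
        flat = np.concatenate([g["a"].ravel(), g["b"].ravel()])
        flat_c = np.concatenate([clipped["a"].ravel(), clipped["b"].ravel()])
        cos = flat @ flat_c / (np.linalg.norm(flat) * np.linalg.norm(flat_c))
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_non_finite_gradient_raises(self):
        with pytest.raises(FloatingPointError):
            clip_gradients({"w": np.array([np.nan])}, 1.0)


class TestGradients:
    def test_analytic_matches_central_finite_differences(self):
        cfg = SkipGRUConfig(hidden_size=2, gate_hidden=3, dropout=0.0, gate_cost=0.01)
        m = init_model(3, 2, cfg, seed=5)
        rng = np.random.default_rng(0)
        X = rng.random((4, 3))
        y = np.array([0, 1, 1, 0])
        _, grads = loss_and_grads(m, X, y)
        eps = 1e-5
        for name, p in m.params().items():
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = loss_and_grads(m, X, y)
                p[idx] = orig - eps
                lm, _ = loss_and_grads(m, X, y)
                p[idx] = orig
                fd = (lp - lm) / (2 * eps)
                g = grads[name][idx]
                assert abs(fd - g) <= 1e-5 * max(1.0, abs(fd)), (name, idx)


class TestTraining:
    def test_learns_separable_data(self):
        ds, _ = planted_dataset(n=625, d=6, informative=(0, 2, 4), effect=4.0, seed=3)
        tr, te = ds.take_rows(np.arange(500)), ds.take_rows(np.arange(500, 625))
        cfg = SkipGRUConfig(hidden_size=32, epochs=60, dropout=0.1,
                            weight_decay=0.01, learning_rate=0.005)
        model, hist = train(tr, config=cfg, seed=0)
        y_pred, _, _ = predict(te.features, model)
        assert (y_pred == te.labels).mean() >= 0.95
        assert max(hist.post_clip_norm) <= cfg.clip_threshold + 1e-9

    def test_same_seed_identical_history(self):
        ds, _ = planted_dataset(n=120, d=4, informative=(0, 2), seed=11)
        cfg = SkipGRUConfig(hidden_size=4, epochs=3, dropout=0.3,
                            learning_rate=0.01, weight_decay=0.01)
        _, h1 = train(ds, config=cfg, seed=2)
        _, h2 = train(ds, config=cfg, seed=2)
        assert abs(h1.loss[-1] - h2.loss[-1]) < 1e-9

    def test_single_class_rejected(self, tiny_config):
        ds, _ = planted_dataset(n=50, d=3, informative=(0,), seed=12)
        one = ds.take_rows(np.flatnonzero(ds.labels == 0))
        with pytest.raises(ValueError):
            train(one, config=tiny_config, seed=0)


class TestPredict:
    def test_argmax_consistency_and_tie_break(self):
        m = init_model(3, 2, SkipGRUConfig(hidden_size=3, dropout=0.0), seed=0)
        m.head.W[:] = 0.0
        m.head.b[:] = 0.0  # uniform probabilities: tie resolved to class 0
        rows = np.random.default_rng(7).random((10, 3))
        idx, probs, _ = predict(rows, m)
        assert np.all(idx == 0)
        np.testing.assert_allclose(probs, 0.5)

    def test_column_mismatch_rejected(self):
        m = init_model(3, 2, SkipGRUConfig(hidden_size=3), seed=0)
        with pytest.raises(ValueError):
            predict(np.ones((2, 5)), m)


class TestGateImportance:
    def test_bounded_and_forced_skip_below_threshold(self):
        m = _forced_gate_model(pi_high=False)
        rows = np.random.default_rng(8).random((30, 4))
        imp = gate_importance(m, rows)
        assert all(0.0 <= v <= 1.0 for v in imp.values())
        assert all(v < m.config.skip_threshold for v in imp.values())

    def test_empty_input_rejected(self):
        m = _forced_gate_model(pi_high=True)
        with pytest.raises(ValueError):
            gate_importance(m, np.empty((0, 4)))

    def test_informative_features_kept_more_than_noise(self):
        hits = 0
        for seed in range(5):
            ds, truth = planted_dataset(n=250, d=6, informative=(1, 4),
                                        effect=2.0, seed=500 + seed)
            cfg = SkipGRUConfig(hidden_size=16, epochs=50, dropout=0.1,
                                weight_decay=0.01, learning_rate=0.005)
            model, _ = train(ds, config=cfg, seed=seed)
            imp = gate_importance(model, ds.features)
            vals = np.array([imp[n] for n in ds.feature_names])
            inf = vals[list(truth.informative)].mean()
            noise = np.delete(vals, list(truth.informative)).mean()
            hits += inf > noise
        assert hits >= 4
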