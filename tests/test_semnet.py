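"""Semantic network: forward pass, trainers, response rule, MI diagnostic."""

import numpy as np
import pandas as pd
import pytest

from relcat.scenarios import SNAKE_WOODS_CONTEXT, build_fixture, network_triples, sample_triples
from relcat.semnet import (
    SemNet,
    TripleCorpus,
    bayes_posterior,
    discrete_entropy,
    discrete_mutual_information,
    layer_mutual_information,
    response_probability,
)


def snake_corpus(seed=7, n=200):
    fx = build_fixture("snake-woods-negative-self")
    df = sample_triples(fx, n, seed=seed, active_context=SNAKE_WOODS_CONTEXT)
    return TripleCorpus.from_frame(df)


class TestForward:
    def test_zero_weights_give_half_everywhere(self):
        net = SemNet(3, (4,), 2, seed=0)
        for w in net.W:
            w[:] = 0.0
        out = net.forward(np.array([1.0, 0.0, 0.0]))
        assert np.allclose(out, 0.5)

    def test_deterministic_given_seed(self):
        a = SemNet(4, (5, 5), 3, n_relations=2, seed=11)
        b = SemNet(4, (5, 5), 3, n_relations=2, seed=11)
        x = np.eye(4)[0]
        r = np.eye(2)[1]
        assert np.array_equal(a.forward(x, r), b.forward(x, r))

    def test_hand_computed_two_layer_composition(self):
        net = SemNet(2, (2,), 1, seed=0)
        net.W[0] = np.array([[1.0, -1.0], [0.5, 0.5]])
        net.W[1] = np.array([[2.0, -1.0]])
        net.b[0] = np.array([0.1, -0.1])
        net.b[1] = np.array([0.2])
        x = np.array([1.0, 0.5])
        s = lambda z: 1.0 / (1.0 + np.exp(-z))
        h = s(np.array([1.0 * 1 - 1.0 * 0.5 + 0.1, 0.5 * 1 + 0.5 * 0.5 - 0.1]))
        expected = s(2.0 * h[0] - 1.0 * h[1] + 0.2)
        assert net.forward(x)[0] == pytest.approx(expected, abs=1e-12)

    def test_outputs_in_unit_interval(self, rng):
        net = SemNet(6, (8, 8), 5, n_relations=3, seed=2)
        out = net.forward(rng.uniform(0, 1, (10, 6)), rng.uniform(0, 1, (10, 3)))
        assert np.all((out > 0) & (out < 1))

    def test_shape_mismatch_rejected(self):
        net = SemNet(3, (4,), 2, seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros(5))


class TestBackprop:
    def test_zero_learning_rate_leaves_weights(self):
        corpus = snake_corpus()
        net = SemNet(len(corpus.concepts), (8,), len(corpus.attributes),
                     n_relations=len(corpus.relations), seed=0)
        before = [w.copy() for w in net.W]
        net.train_backprop(corpus, epochs=3, lr=0.0, seed=0)
        assert all(np.array_equal(a, b) for a, b in zip(before, net.W))

    def test_single_example_drives_loss_to_zero(self):
        df = pd.DataFrame({"concept": ["a"], "relation": ["coordination"], "attribute": ["x"]})
        corpus = TripleCorpus.from_frame(df)
        net = SemNet(1, (4,), 1, n_relations=1, seed=1)
        trace = net.train_backprop(corpus, epochs=2000, lr=1.0, seed=1)
        assert trace[-1] < 1e-3

    def test_separable_corpus_trains_to_high_accuracy(self):
        corpus = snake_corpus()
        net = SemNet(len(corpus.concepts), (16, 16), len(corpus.attributes),
                     n_relations=len(corpus.relations), seed=7)
        net.train_backprop(corpus, epochs=2000, lr=0.8, seed=7, batch_size=32)
        assert net.accuracy(corpus) >= 0.95

    def test_gradients_match_finite_differences(self, rng):
        net = SemNet(3, (4,), 2, n_relations=2, seed=3)
        x = rng.uniform(0, 1, (5, 3))
        r = rng.uniform(0, 1, (5, 2))
        t = rng.uniform(0, 1, (5, 2))
        gW, gb, gWr = net.gradients(x, r, t)
        eps = 1e-6
        for (i, j) in [(0, 1), (1, 2)]:
            net.W[0][i, j] += eps
            up = net.loss(x, r, t)
            net.W[0][i, j] -= 2 * eps
            down = net.loss(x, r, t)
            net.W[0][i, j] += eps
            assert gW[0][i, j] == pytest.approx((up - down) / (2 * eps), rel=1e-4)


class TestPredictiveCoding:
    def test_zero_error_zero_update(self):
        net = SemNet(3, (4,), 2, seed=5)
        x = np.array([[0.3, 0.6, 0.1]])
        t = np.atleast_2d(net.forward(x))  # target equals prediction
        dW, db, _ = net.pc_updates(x, None, t, max_iter=500, tol=1e-10)
        assert all(np.allclose(d, 0.0, atol=1e-8) for d in dW + db)

    def test_linear_single_layer_equals_delta_rule(self, rng):
        net = SemNet(4, (), 3, seed=2, activation="linear")
        x = rng.uniform(-1, 1, (6, 4))
        t = rng.uniform(-1, 1, (6, 3))
        dW, db, _ = net.pc_updates(x, None, t, max_iter=200, tol=1e-12)
        pred = np.atleast_2d(net.forward(x))
        delta = (t - pred).T @ x / 6.0  # the Widrow-Hoff step
        assert np.allclose(dW[0], delta, atol=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_updates_align_with_backprop_gradients(self, seed):
        """Relaxed local updates track the exact gradient on 5-8-4 nets."""
        rng = np.random.default_rng(1000 + seed)
        net = SemNet(5, (8,), 4, seed=seed)
        x = rng.uniform(0, 1, (8, 5))
        t = rng.uniform(0, 1, (8, 4))
        gW, gb, _ = net.gradients(x, None, t)
        dW, db, _ = net.pc_updates(x, None, t, step=0.1, max_iter=5000, tol=1e-6)
        grad = np.concatenate([g.ravel() for g in gW + gb])
        pc = np.concatenate([d.ravel() for d in dW + db])
        assert np.corrcoef(-grad, pc)[0, 1] >= 0.99

    def test_pc_training_reduces_loss(self):
        corpus = snake_corpus(n=120)
        net = SemNet(len(corpus.concepts), (12,), len(corpus.attributes),
                     n_relations=len(corpus.relations), seed=4)
        trace = net.train_predictive_coding(
            corpus, epochs=30, lr=0.5, seed=4, batch_size=32, relax_iter=100
        )
        assert trace[-1] < trace[0]


class TestResponseRule:
    def test_zero_activation_gives_half(self):
        assert response_probability(0.0, theta=1.0) == pytest.approx(0.5)

    def test_printed_value_theta_two(self):
        assert response_probability(1.0, theta=2.0) == pytest.approx(0.8807970779778823, abs=1e-12)

    def test_limit_and_monotonicity(self):
        assert response_probability(1.0, theta=500.0) == pytest.approx(1.0)
        grid = np.linspace(-2, 2, 9)
        vals = response_probability(grid, theta=1.3)
        assert np.all(np.diff(vals) > 0)

    def test_theta_must_be_positive(self):
        with pytest.raises(ValueError):
            response_probability(0.5, theta=0.0)

    def test_bayes_identity_on_discrete_tables(self, rng):
        p_h = rng.uniform(0.1, 0.9)
        p_e_given_h = rng.uniform(0.1, 0.9)
        p_e_given_not = rng.uniform(0.1, 0.9)
        p_e = p_e_given_h * p_h + p_e_given_not * (1 - p_h)
        post = bayes_posterior(p_e_given_h, p_h, p_e)
        assert post * p_e == pytest.approx(p_e_given_h * p_h, abs=1e-12)


class TestMutualInformation:
    def test_identity_copy_has_entropy_of_input(self, rng):
        xs = rng.integers(0, 4, 200)
        assert discrete_mutual_information(xs, xs) == pytest.approx(discrete_entropy(xs))

    def test_independent_streams_near_zero(self, rng):
        xs = rng.integers(0, 2, 5000)
        ys = rng.integers(0, 2, 5000)
        assert discrete_mutual_information(xs, ys) < 0.01

    def test_small_joint_table_matches_double_sum(self):
        xs = [0, 0, 1, 1, 1, 2]
        ys = ["a", "b", "a", "a", "b", "b"]
        joint = {}
        for x, y in zip(xs, ys):
            joint[(x, y)] = joint.get((x, y), 0) + 1 / len(xs)
        px = {x: sum(v for (a, _), v in joint.items() if a == x) for x in set(xs)}
        py = {y: sum(v for (_, b), v in joint.items() if b == y) for y in set(ys)}
        expected = sum(
            v * np.log2(v / (px[x] * py[y])) for (x, y), v in joint.items()
        )
        assert discrete_mutual_information(xs, ys) == pytest.approx(expected, abs=1e-12)

    def test_layer_mi_nonnegative_and_dpi_along_chain(self):
        # a pure chain (no mid-network relation injection), so the hidden
        # layers form a Markov chain in the input and the DPI applies
        df = pd.DataFrame({
            "concept": ["a", "a", "b", "b", "c", "c", "d", "d"] * 25,
            "relation": ["r"] * 200,
            "attribute": ["x", "y", "x", "z", "y", "z", "x", "y"] * 25,
        })
        corpus = TripleCorpus.from_frame(df)
        net = SemNet(len(corpus.concepts), (10, 10), len(corpus.attributes),
                     n_relations=len(corpus.relations), seed=9)
        net.train_backprop(corpus, epochs=300, lr=0.8, seed=9, batch_size=32)
        i_x1, i_1y = layer_mutual_information(net, corpus, layer_index=1, n_bins=4)
        i_x2, i_2y = layer_mutual_information(net, corpus, layer_index=2, n_bins=4)
        assert min(i_x1, i_1y, i_x2, i_2y) >= 0.0
        h_x = discrete_entropy(list(df["concept"]))
        assert i_x1 <= h_x + 1e-9 and i_x2 <= h_x + 1e-9
        # data-processing: deeper layer knows no more about the input
        assert i_x2 <= i_x1 + 1e-9

    def test_constant_layer_reports_zero(self):
        corpus = snake_corpus(n=50)
        net = SemNet(len(corpus.concepts), (6,), len(corpus.attributes),
                     n_relations=len(corpus.relations), seed=0)
        net.W[0][:] = 0.0
        net.Wr[:] = 0.0
        i_xh, i_hy = layer_mutual_information(net, corpus, layer_index=1)
        assert i_xh == pytest.approx(0.0, abs=1e-12)
        assert i_hy == pytest.approx(0.0, abs=1e-12)


class TestCheckpoint:
    def test_json_round_trip_preserves_function(self, tmp_path, rng):
        net = SemNet(4, (6, 5), 3, n_relations=2, seed=13)
        path = tmp_path / "model.json"
        net.to_json(path)
        clone = SemNet.from_json(path)
        x = rng.uniform(0, 1, (3, 4))
        r = rng.uniform(0, 1, (3, 2))
        assert np.allclose(net.forward(x, r), clone.forward(x, r), atol=1e-15)
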