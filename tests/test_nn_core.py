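"""Learning primitives pinned to independent scalar-loop oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgbeats import nn_core as nn


def scalar_lstm_step(p, x, h_prev, c_prev):
    """Independent scalar-loop oracle for one LSTM step (no vectorization)."""
    m, n = p.Wf.shape
    sg = lambda z: 1.0 / (1.0 + math.exp(-z))
    h = np.zeros(m)
    c = np.zeros(m)
    for j in range(m):
        zf = sum(p.Wf[j, k] * x[k] for k in range(n)) + \
            sum(p.Uf[j, k] * h_prev[k] for k in range(m)) + p.bf[j]
        zi = sum(p.Wi[j, k] * x[k] for k in range(n)) + \
            sum(p.Ui[j, k] * h_prev[k] for k in range(m)) + p.bi[j]
        zc = sum(p.Wc[j, k] * x[k] for k in range(n)) + \
            sum(p.Uc[j, k] * h_prev[k] for k in range(m)) + p.bc[j]
        zo = sum(p.Wo[j, k] * x[k] for k in range(n)) + \
            sum(p.Uo[j, k] * h_prev[k] for k in range(m)) + p.bo[j]
        f, i, o = sg(zf), sg(zi), sg(zo)
        g = math.tanh(zc)
        c[j] = f * c_prev[j] + i * g
        h[j] = o * math.tanh(c[j])
    return h, c


def random_params(rng, n=2, m=2):
    return nn.LstmCellParams(
        *(rng.standard_normal(s) for s in
          [(m, n)] * 4 + [(m, m)] * 4 + [(m,)] * 4))


class TestLstmCell:
    def test_zero_weights_half_gates(self):
        p = nn.LstmCellParams.zeros(3, 2)
        c_prev = np.array([0.4, -1.2])
        st_ = nn.lstm_cell_step(p, np.ones(3), np.zeros(2), c_prev)
        assert np.allclose(st_.f, 0.5) and np.allclose(st_.i, 0.5)
        assert np.allclose(st_.o, 0.5) and np.allclose(st_.c_tilde, 0.0)
        assert np.allclose(st_.c, 0.5 * c_prev)
        assert np.allclose(st_.h, 0.5 * np.tanh(0.5 * c_prev))

    def test_zero_weights_zero_state_fixed_point(self):
        p = nn.LstmCellParams.zeros(3, 2)
        st_ = nn.lstm_cell_step(p, np.ones(3), np.zeros(2), np.zeros(2))
        assert np.allclose(st_.h, 0.0) and np.allclose(st_.c, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_match_scalar_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = random_params(rng)
        x = rng.standard_normal(2)
        h0 = rng.standard_normal(2)
        c0 = rng.standard_normal(2)
        st_ = nn.lstm_cell_step(p, x, h0, c0)
        h_ref, c_ref = scalar_lstm_step(p, x, h0, c0)
        assert np.max(np.abs(st_.h - h_ref)) < 1e-10
        assert np.max(np.abs(st_.c - c_ref)) < 1e-10

    def test_shape_mismatch_names_offender(self):
        p = nn.LstmCellParams.zeros(3, 2)
        with pytest.raises(ValueError, match="x must"):
            nn.lstm_cell_step(p, np.zeros(4), np.zeros(2), np.zeros(2))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_gate_boundedness(self, seed):
        """Gates stay in (0,1), the candidate in (-1,1), for any inputs."""
        # moderate magnitudes: the open-interval bound holds mathematically
        # for any finite input but float64 saturates past |z| ~ 37
        rng = np.random.default_rng(seed)
        p = random_params(rng, 3, 4)
        st_ = nn.lstm_cell_step(p, rng.standard_normal(3),
                                rng.standard_normal(4),
                                rng.standard_normal(4))
        for gate in (st_.f, st_.i, st_.o):
            assert np.all(gate > 0) and np.all(gate < 1)
        assert np.all(np.abs(st_.c_tilde) < 1)


class TestLstmLayer:
    def test_length_one_sequence_both_modes_agree(self, rng):
        p = random_params(rng, 2, 3)
        x = rng.standard_normal((1, 2))
        seq = nn.lstm_layer_forward(p, x, return_sequences=True)
        final = nn.lstm_layer_forward(p, x, return_sequences=False)
        assert np.array_equal(seq[0], final)

    def test_zero_weights_zero_outputs(self):
        p = nn.LstmCellParams.zeros(2, 3)
        out = nn.lstm_layer_forward(p, np.ones((4, 2)))
        assert np.allclose(out, 0.0)

    def test_length_three_matches_unrolled_cell_steps(self, rng):
        p = random_params(rng, 2, 3)
        x = rng.standard_normal((3, 2))
        out = nn.lstm_layer_forward(p, x)
        h = np.zeros(3)
        c = np.zeros(3)
        for t in range(3):
            st_ = nn.lstm_cell_step(p, x[t], h, c)
            h, c = st_.h, st_.c
            assert np.array_equal(out[t], h)

    def test_batched_layer_matches_functional_form(self, rng):
        layer = nn.Lstm(3, 4, rng=np.random.default_rng(5))
        x = rng.standard_normal((2, 6, 3))
        batched = layer.forward(x)
        p = layer.cell_params()
        for b in range(2):
            assert np.max(np.abs(batched[b] - nn.lstm_layer_forward(p, x[b]))) \
                < 1e-12

    def test_empty_sequence_rejected(self, rng):
        p = random_params(rng)
        with pytest.raises(ValueError):
            nn.lstm_layer_forward(p, np.empty((0, 2)))


class TestAdam:
    def test_zero_gradient_never_moves(self):
        s = nn.AdamState(theta=np.array([1.0, -2.0]))
        for _ in range(10):
            nn.adam_step(s, np.zeros(2))
        assert np.array_equal(s.theta, [1.0, -2.0])

    def test_first_step_size(self):
        s = nn.AdamState(theta=np.array([0.0]))
        nn.adam_step(s, np.array([1.0]))
        assert s.theta[0] == pytest.approx(-0.001 / (1 + 1e-8), abs=1e-12)

    def test_two_steps_constant_gradient_closed_form(self):
        # hand evaluation of the moment/bias-correction recursions, g = 0.5
        alpha, b1, b2, eps = 0.001, 0.9, 0.999, 1e-8
        g = 0.5
        theta = 0.2
        m = v = 0.0
        for t in (1, 2):
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            theta -= alpha * (m / (1 - b1 ** t)) / \
                (math.sqrt(v / (1 - b2 ** t)) + eps)
        s = nn.AdamState(theta=np.array([0.2]))
        nn.adam_step(s, np.array([g]))
        nn.adam_step(s, np.array([g]))
        assert abs(s.theta[0] - theta) < 1e-12
        assert s.t == 2

    def test_step_bounded_by_alpha_when_beta1_zero(self, rng):
        s = nn.AdamState(theta=np.zeros(50), beta1=0.0)
        nn.adam_step(s, rng.standard_normal(50) * 100)
        assert np.all(np.abs(s.theta) <= 0.001 + 1e-12)

    def test_non_finite_gradient_rejected(self):
        s = nn.AdamState(theta=np.zeros(2))
        with pytest.raises(FloatingPointError):
            nn.adam_step(s, np.array([1.0, np.nan]))


class TestEarlyStopping:
    def test_strictly_decreasing_never_stops(self):
        losses = [1.0 / (k + 1) for k in range(50)]
        stop, best = nn.early_stopper(losses, patience=5)
        assert stop is None and best == 50

    def test_plateau_example(self):
        losses = [1.0, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9]
        stop, best = nn.early_stopper(losses, patience=5)
        assert (stop, best) == (7, 2)

    def test_patience_zero_stops_at_first_non_improvement(self):
        stop, best = nn.early_stopper([1.0, 0.5, 0.6, 0.4], patience=0)
        assert (stop, best) == (3, 2)

    def test_streaming_form_agrees(self):
        losses = [1.0, 0.8, 0.85, 0.83, 0.84, 0.86, 0.9]
        stopper = nn.EarlyStopper(patience=3)
        stopped_at = None
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(loss):
                stopped_at = epoch
                break
        assert (stopped_at, stopper.best_epoch) == \
            nn.early_stopper(losses, patience=3)


class TestDenseDropout:
    def test_zero_weights_relu_gives_zero(self):
        out = nn.dense_forward(np.zeros((4, 3)), np.zeros(3), "relu",
                               np.ones((2, 4)))
        assert np.allclose(out, 0.0)

    def test_softmax_equal_logits_uniform(self):
        out = nn.dense_forward(np.zeros((4, 5)), np.full(5, 3.0), "softmax",
                               np.ones((2, 4)))
        assert np.allclose(out, 0.2, atol=1e-12)

    def test_softmax_normalization(self, rng):
        w = rng.standard_normal((4, 5))
        out = nn.dense_forward(w, rng.standard_normal(5), "softmax",
                               rng.standard_normal((7, 4)))
        assert np.max(np.abs(out.sum(axis=1) - 1.0)) < 1e-12

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            nn.dense_forward(np.zeros((4, 3)), np.zeros(3), "relu",
                             np.ones((2, 5)))

    def test_dropout_rate_zero_and_inference_are_identity(self, rng):
        assert np.all(nn.dropout_mask(0.0, (10,), rng) == 1.0)
        assert np.all(nn.dropout_mask(0.5, (10,), rng, training=False) == 1.0)

    def test_dropout_empirical_rate(self):
        rng = np.random.default_rng(0)
        mask = nn.dropout_mask(0.1, (100_000,), rng)
        assert np.mean(mask == 0.0) == pytest.approx(0.1, abs=0.01)
        # kept entries carry the inverted scaling
        assert np.allclose(mask[mask > 0], 1.0 / 0.9)

    def test_dropout_rate_one_rejected(self, rng):
        with pytest.raises(ValueError):
            nn.dropout_mask(1.0, (5,), rng)


class TestBackpropagation:
    """Analytic gradients vs central differences on tiny networks."""

    @staticmethod
    def numeric_check(net, loss, x, y, atol=1e-5):
        pred = net.forward(x, training=True)
        net.backward(loss.grad(pred, y))
        grads = [g.copy() for g in net.grads()]
        rng = np.random.default_rng(0)
        eps = 1e-6
        worst = 0.0
        for p, g in zip(net.params(), grads):
            flat = p.reshape(-1)
            for idx in rng.choice(flat.size, size=min(8, flat.size),
                                  replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss.value(net.forward(x, training=False), y)
                flat[idx] = old - eps
                lm = loss.value(net.forward(x, training=False), y)
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                worst = max(worst, abs(num - g.reshape(-1)[idx]))
        assert worst < atol

    def test_lstm_autoencoder_gradients(self, rng):
        net = nn.Sequential([
            nn.Lstm(1, 3, rng=np.random.default_rng(2)),
            nn.TimeDistributedDense(3, 1, rng=np.random.default_rng(3))])
        x = rng.standard_normal((2, 5, 1))
        self.numeric_check(net, nn.MeanSquaredError(), x,
                           rng.standard_normal((2, 5, 1)))

    def test_classifier_stack_gradients(self, rng):
        net = nn.Sequential([
            nn.Lstm(1, 2, rng=np.random.default_rng(4)),
            nn.Flatten(),
            nn.Dense(10, 4, activation="relu", rng=np.random.default_rng(5)),
            nn.Dense(4, 3, rng=np.random.default_rng(6))])
        x = rng.standard_normal((3, 5, 1))
        y = np.eye(3)
        self.numeric_check(net, nn.SoftmaxCrossEntropy(), x, y)


class TestTraining:
    def test_training_decreases_reconstruction_loss(self, tiny_dataset):
        """Learn to reconstruct 10 beats; loss after training < initial loss."""
        from ecgbeats.records import beats_to_array

        _, beats = tiny_dataset
        x, _ = beats_to_array(beats[:10])
        x = x[:, :, None]
        net = nn.Sequential([
            nn.Lstm(1, 6, rng=np.random.default_rng(1)),
            nn.TimeDistributedDense(6, 1, rng=np.random.default_rng(2))])
        cfg = nn.TrainingConfig(epochs=50, batch_size=5, patience=50,
                                validation_fraction=0.0, seed=0)
        hist = nn.fit(net, x, x, nn.MeanSquaredError(), cfg)
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_fit_is_deterministic_given_seed(self, rng):
        x = rng.standard_normal((12, 4, 1))

        def run():
            net = nn.Sequential([
                nn.Lstm(1, 3, rng=np.random.default_rng(7)),
                nn.TimeDistributedDense(3, 1, rng=np.random.default_rng(8))])
            cfg = nn.TrainingConfig(epochs=3, batch_size=4, patience=3, seed=5)
            hist = nn.fit(net, x, x, nn.MeanSquaredError(), cfg)
            return hist.train_loss

        assert run() == run()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            nn.TrainingConfig(epochs=0)
        with pytest.raises(ValueError):
            nn.TrainingConfig(epochs=5, patience=10)
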