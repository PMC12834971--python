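"""Autodiff engine, LSTM cell mathematics and optimisers."""

import math

import numpy as np
import pytest

from bidirmol.nn import (Adam, AdamW, BatchNorm, LSTMCell, LSTMGateParams,
                         Linear, Tensor, concat, lstm_cell_step, no_grad,
                         stack, uniform_init)
from bidirmol.models import temperature_softmax


def scalar_lstm_oracle(x, h_prev, c_prev, p: LSTMGateParams):
    """Independent element-by-element evaluation of the gate equations."""
    H = p.b_i.data.size
    n_in = p.W_i.data.shape[0]

    def sig(v):
        return 1.0 / (1.0 + math.exp(-v))

    h_out = np.zeros(H)
    c_out = np.zeros(H)
    for j in range(H):
        zi = p.b_i.data[j]
        zf = p.b_f.data[j]
        zo = p.b_o.data[j]
        zc = p.b_c.data[j]
        for a in range(n_in):
            zi += p.W_i.data[a, j] * x[a]
            zf += p.W_f.data[a, j] * x[a]
            zo += p.W_o.data[a, j] * x[a]
            zc += p.W_c.data[a, j] * x[a]
        for a in range(H):
            zi += p.U_i.data[a, j] * h_prev[a]
            zf += p.U_f.data[a, j] * h_prev[a]
            zo += p.U_o.data[a, j] * h_prev[a]
            zc += p.U_c.data[a, j] * h_prev[a]
        i, f, o = sig(zi), sig(zf), sig(zo)
        c_tilde = math.tanh(zc)
        c_out[j] = f * c_prev[j] + i * c_tilde
        h_out[j] = o * math.tanh(c_out[j])
    return h_out, c_out


class TestLSTMCell:
    def _zero_cell(self, n_in=3, hidden=4):
        cell = LSTMCell(n_in, hidden, np.random.default_rng(0))
        for p in cell.parameters():
            p.data[:] = 0.0
        return cell

    def test_all_zero_weights_zero_state(self):
        cell = self._zero_cell()
        h, c = cell(Tensor(np.zeros((1, 3))), *cell.zero_state(1))
        assert np.allclose(c.data, 0.0)
        assert np.allclose(h.data, 0.0)

    def test_all_zero_weights_nonzero_cell(self):
        # gates are all 1/2 so c' = v/2 and h' = tanh(v/2)/2
        cell = self._zero_cell()
        v = np.array([[0.3, -1.2, 2.0, 0.01]])
        h, c = cell(Tensor(np.zeros((1, 3))), Tensor(np.zeros((1, 4))),
                    Tensor(v))
        assert np.allclose(c.data, 0.5 * v)
        assert np.allclose(h.data, 0.5 * np.tanh(0.5 * v))

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            cell = LSTMCell(3, 5, np.random.default_rng(rng.integers(2**31)))
            x = rng.normal(size=3)
            h0 = rng.normal(size=5)
            c0 = rng.normal(size=5)
            h, c = cell(Tensor(x[None]), Tensor(h0[None]), Tensor(c0[None]))
            h_ref, c_ref = scalar_lstm_oracle(x, h0, c0, cell.gates)
            assert np.abs(h.data[0] - h_ref).max() < 1e-6
            assert np.abs(c.data[0] - c_ref).max() < 1e-6

    def test_hidden_state_bounded(self):
        rng = np.random.default_rng(1)
        cell = LSTMCell(2, 6, rng)
        h, c = cell.zero_state(4)
        for _ in range(20):
            h, c = cell(Tensor(rng.normal(size=(4, 2)) * 5), h, c)
        assert (np.abs(h.data) < 1.0).all()

    def test_dimension_mismatch_rejected(self):
        cell = LSTMCell(3, 4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            cell(Tensor(np.zeros((1, 5))), *cell.zero_state(1))


class TestTemperatureSoftmax:
    def test_equal_logits_uniform(self):
        for T in (0.25, 1.0, 4.0):
            p = temperature_softmax(np.zeros(7), T)
            assert np.allclose(p, 1 / 7)

    def test_direct_evaluation(self):
        p = temperature_softmax(np.array([0.0, np.log(3.0)]), 1.0)
        assert np.allclose(p, [0.25, 0.75])

    def test_high_temperature_limit(self):
        y = np.random.default_rng(0).normal(size=9)
        p = temperature_softmax(y, 1e9)
        assert np.abs(p - 1 / 9).max() < 1e-8

    def test_simplex_for_extreme_logits(self):
        y = np.array([1e4, -1e4, 0.0])
        for T in (0.25, 1.0, 4.0):
            p = temperature_softmax(y, T)
            assert np.isfinite(p).all() and abs(p.sum() - 1.0) < 1e-12
            assert (p >= 0).all()

    def test_lower_temperature_sharpens_argmax(self):
        y = np.array([0.1, 1.3, -0.4, 0.9])
        p_hot = temperature_softmax(y, 2.0)
        p_cold = temperature_softmax(y, 0.5)
        assert p_cold[1] > p_hot[1]

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            temperature_softmax(np.zeros(3), 0.0)


def _numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x.data)
    it = np.nditer(x.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x.data[i] += eps
        fp = f()
        x.data[i] -= 2 * eps
        fm = f()
        x.data[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestAutodiff:
    def test_composite_graph_gradients(self):
        rng = np.random.default_rng(0)
        cell = LSTMCell(3, 4, rng)
        lin = Linear(4, 5, rng)
        bn = BatchNorm(4)
        bn.set_train(True)
        x = Tensor(rng.normal(size=(6, 3)), requires_grad=True)
        idx = rng.integers(0, 5, size=6)

        def loss():
            h, c = cell.zero_state(6)
            h, c = cell(x, h, c)
            h, c = cell(x * 0.5, h, c)
            z = lin(bn(h))
            lp = z.log_softmax(-1)
            return -(lp.gather(idx)).mean() + (z**2).sum() * 0.01

        loss().backward()
        for p in [x, cell.W_i, cell.U_c, cell.b_f, lin.W, lin.b,
                  bn.gamma, bn.beta]:
            num = _numeric_grad(lambda: loss().item(), p)
            assert np.abs(num - p.grad).max() < 1e-5

    def test_no_grad_suppresses_graph(self):
        x = Tensor(np.ones(3), requires_grad=True)
        with no_grad():
            y = (x * 2.0).sum()
        assert y._backward is None and not y.requires_grad

    def test_concat_stack_slice_shapes(self):
        a = Tensor(np.ones((2, 3)), requires_grad=True)
        b = Tensor(np.ones((2, 2)), requires_grad=True)
        c = concat([a, b], axis=1)
        assert c.shape == (2, 5)
        s = stack([a, a], axis=1)
        assert s.shape == (2, 2, 3)
        c.sum().backward()
        assert a.grad.shape == (2, 3) and b.grad.shape == (2, 2)


class TestBatchNorm:
    def test_train_normalises_batch(self):
        bn = BatchNorm(3)
        bn.set_train(True)
        x = np.random.default_rng(0).normal(loc=5, scale=2, size=(200, 3))
        y = bn(Tensor(x)).data
        assert np.abs(y.mean(axis=0)).max() < 1e-8
        assert np.abs(y.std(axis=0) - 1).max() < 1e-2

    def test_eval_is_deterministic_affine(self):
        bn = BatchNorm(3)
        bn.set_train(True)
        rng = np.random.default_rng(0)
        for _ in range(50):
            bn(Tensor(rng.normal(loc=2, size=(64, 3))))
        bn.set_train(False)
        x = Tensor(rng.normal(size=(8, 3)))
        y1, y2 = bn(x).data, bn(x).data
        assert np.array_equal(y1, y2)
        # running statistics converge on the data distribution
        assert np.abs(bn.running_mean - 2).max() < 0.3


class TestOptimisers:
    def test_adamw_decay_is_decoupled(self):
        p = Tensor(np.ones(4), requires_grad=True)
        opt = AdamW([p], lr=0.1, weight_decay=0.5)
        p.grad = np.zeros(4)
        opt.step()
        # zero gradient: only the decay term moves the weights
        assert np.allclose(p.data, 1.0 - 0.1 * 0.5 * 1.0)

    def test_adam_descends_quadratic(self):
        p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = Adam([p], lr=0.1)
        for _ in range(500):
            opt.zero_grad()
            ((p * p).sum()).backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-3

    def test_uniform_init_bounds(self):
        t = uniform_init(np.random.default_rng(0), (100, 100), 100)
        assert np.abs(t.data).max() <= 0.1
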