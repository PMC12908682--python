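"""Gradient and behavior checks for the autodiff core and layers."""

import numpy as np
import pytest

from epintlm.nn import (Adam, BatchNorm1d, BiGRU, Dense, Dropout,
                        MultiHeadAttention, Tensor, no_grad)
from epintlm.nn import autograd as ag


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g


def check_grads(op, *shapes, seed=0, tol=1e-5):
    rng = np.random.default_rng(seed)
    arrays = [rng.normal(size=s) for s in shapes]
    tensors = [Tensor(a.copy(), requires_grad=True) for a in arrays]
    out = op(*tensors)
    (out.sum() if out.data.size > 1 else out).backward()
    for k, (t, a) in enumerate(zip(tensors, arrays)):
        def scalar(x, k=k):
            args = [Tensor(v.copy()) for v in arrays]
            args[k] = Tensor(x)
            return float(op(*args).data.sum())
        num = numeric_grad(scalar, a)
        assert np.allclose(t.grad, num, atol=tol, rtol=tol), \
            f"gradient mismatch for argument {k} of {op}"


@pytest.mark.parametrize("op,shapes", [
    (lambda a, b: a + b, [(3, 4), (4,)]),                     # broadcast add
    (lambda a, b: a * b, [(3, 1, 4), (2, 4)]),                # broadcast mul
    (lambda a, b: ag.matmul(a, b), [(2, 3, 4), (4, 5)]),      # batched matmul
    (lambda a: ag.softmax(a, axis=-1), [(2, 5)]),
    (lambda a: ag.relu(a) + ag.sigmoid(a) * ag.tanh(a), [(4, 3)]),
    (lambda a: ag.maxpool1d(a, 3), [(2, 10, 3)]),
    (lambda a, w, b: ag.conv1d(a, w, b), [(2, 9, 3), (4, 3, 5), (5,)]),
    (lambda a, b: ag.concat([a, b], axis=1), [(2, 3, 4), (2, 2, 4)]),
    (lambda a: a[:, 1:3, :] * 2.0 + a[:, 0:1, :], [(2, 5, 3)]),
    (lambda a: ag.power(a * a + 1.0, -0.5), [(3, 3)]),
    (lambda a: ag.log(ag.exp(a) + 1.0).mean(), [(4,)]),
])
def test_primitive_gradients_match_finite_differences(op, shapes):
    check_grads(op, *shapes)


def test_gru_sequence_gradients():
    check_grads(lambda xp, w, b: ag.gru_sequence(xp, w, b),
                (2, 4, 9), (3, 9), (9,), tol=1e-4)
    check_grads(lambda xp, w, b: ag.gru_sequence(xp, w, b, reverse=True),
                (2, 4, 9), (3, 9), (9,), tol=1e-4)


def test_embedding_gather_and_scatter():
    rng = np.random.default_rng(0)
    E = Tensor(rng.normal(size=(7, 3)), requires_grad=True)
    idx = np.array([[0, 6, 2], [2, 2, 5]])
    out = ag.embedding(E, idx)
    assert np.array_equal(out.data, E.data[idx])
    g = rng.normal(size=out.shape)
    out.backward(g)
    expected = np.zeros((7, 3))
    np.add.at(expected, idx.ravel(), g.reshape(-1, 3))
    assert np.allclose(E.grad, expected)


def test_shared_subexpression_accumulates_once_per_path():
    x = Tensor(np.array([2.0]), requires_grad=True)
    y = x * 3.0
    z = y + y * y           # z = 3x + 9x^2 -> dz/dx = 3 + 18x = 39
    z.backward(np.array([1.0]))
    assert np.allclose(x.grad, [39.0])


def test_no_grad_suppresses_tape():
    x = Tensor(np.ones(3), requires_grad=True)
    with no_grad():
        y = x * 2.0 + 1.0
    assert y._parents == ()
    assert y._backward is None


class TestLayers:
    def test_bigru_output_shape_and_determinism(self, rng):
        layer = BiGRU(6, 4, layers=2, rng=np.random.default_rng(0))
        x = Tensor(rng.normal(size=(3, 10, 6)).astype(np.float32))
        out1 = layer(x)
        out2 = layer(x)
        assert out1.shape == (3, 10, 8)
        assert np.array_equal(out1.data, out2.data)

    def test_gru_direction_symmetry(self):
        """Running the reversed input through a forward GRU equals
        reversing the output of the backward GRU with tied weights."""
        from epintlm.nn.layers import GRU
        fwd = GRU(5, 4, np.random.default_rng(3), reverse=False)
        bwd = GRU(5, 4, np.random.default_rng(3), reverse=True)  # same init
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 9, 5)).astype(np.float32)
        out_f = fwd(Tensor(x[:, ::-1, :].copy())).data
        out_b = bwd(Tensor(x)).data
        assert np.allclose(out_f[:, ::-1, :], out_b, atol=1e-5)

    def test_zero_weight_gru_zero_input_zero_output(self):
        from epintlm.nn.layers import GRU
        g = GRU(4, 3, np.random.default_rng(0))
        for p in g.parameters():
            p.data[...] = 0.0
        out = g(Tensor(np.zeros((2, 5, 4), dtype=np.float32)))
        assert np.allclose(out.data, 0.0)

    def test_batchnorm_train_and_eval(self, rng):
        bn = BatchNorm1d(4)
        x = Tensor(rng.normal(2.0, 3.0, size=(8, 10, 4)).astype(np.float32))
        out = bn(x)
        # batch statistics: normalized output has ~zero mean, unit var
        assert np.allclose(out.data.mean(axis=(0, 1)), 0.0, atol=1e-4)
        assert np.allclose(out.data.std(axis=(0, 1)), 1.0, atol=1e-3)
        for _ in range(300):
            bn(x)
        bn.eval()
        out_eval = bn(x)
        # running stats converge to batch stats for a constant batch
        assert np.allclose(out_eval.data.mean(axis=(0, 1)), 0.0, atol=1e-2)

    def test_dropout_modes(self, rng):
        drop = Dropout(0.5, np.random.default_rng(0))
        x = Tensor(np.ones((4, 100), dtype=np.float32))
        out = drop(x)
        kept = out.data != 0
        assert 0.2 < kept.mean() < 0.8
        assert np.allclose(out.data[kept], 2.0)  # inverted scaling
        drop.eval()
        assert np.array_equal(drop(x).data, x.data)

    def test_attention_rows_sum_to_one(self, rng):
        attn = MultiHeadAttention(8, 2, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(2, 5, 8)).astype(np.float32))
        _, w = attn(x)
        assert w.shape == (2, 2, 5, 5)
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-5)
        assert (w >= 0).all()


def test_adam_minimizes_quadratic():
    w = Tensor(np.array([5.0, -3.0]), requires_grad=True)
    opt = Adam([w], lr=0.1)
    for _ in range(200):
        loss = (w * w).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.allclose(w.data, 0.0, atol=1e-2)


def test_adam_weight_decay_shrinks_unused_weights():
    w = Tensor(np.array([1.0]), requires_grad=True)
    opt = Adam([w], lr=0.01, weight_decay=1.0)
    for _ in range(100):
        loss = w * Tensor(np.array([0.0]))
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert abs(float(w.data[0])) < 0.75
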