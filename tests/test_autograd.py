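"""Finite-difference checks of the autodiff engine and layer gradients."""

import numpy as np
import pytest

from fundusseg.autograd import Tensor, concatenate, maximum, no_grad
from fundusseg import nn


def numeric_grad(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    g = np.zeros_like(x)
    flat, gf = x.reshape(-1), g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        up = f(x)
        flat[i] = orig - eps
        dn = f(x)
        flat[i] = orig
        gf[i] = (up - dn) / (2 * eps)
    return g


def check_op(op, *shapes, seed=0, tol=1e-4):
    rng = np.random.default_rng(seed)
    args = [rng.standard_normal(s) for s in shapes]
    out0 = op(*[Tensor(a) for a in args])
    w = rng.standard_normal(out0.shape)

    for i in range(len(args)):
        def scalar(xi, i=i):
            vals = [Tensor(a) for a in args]
            vals[i] = Tensor(xi)
            return float((op(*vals) * Tensor(w)).sum())

        ts = [Tensor(a, requires_grad=(j == i)) for j, a in enumerate(args)]
        (op(*ts) * Tensor(w)).sum().backward()
        num = numeric_grad(scalar, args[i].copy())
        assert np.abs(ts[i].grad - num).max() < tol


@pytest.mark.parametrize("op,shapes", [
    (lambda a, b: a @ b, [(3, 4), (4, 2)]),
    (lambda a, b: a @ b, [(2, 3, 4), (4, 5)]),         # broadcast matmul
    (lambda a, b: a * b + a / (b * b + 3.0), [(4, 5), (4, 5)]),
    (lambda a: a.sigmoid().log(), [(6,)]),
    (lambda a: a.gelu(), [(7,)]),
    (lambda a: a.relu() + a.tanh() + a.exp(), [(5,)]),
    (lambda a: ((a * a).sum(axis=1, keepdims=True) + 1e-6) ** 0.5, [(3, 4)]),
    (lambda a, b: maximum(a, b), [(8,), (8,)]),
    (lambda a: a.reshape(2, 6).transpose((1, 0)).mean(axis=0), [(3, 4)]),
    (lambda a: a.pad(((1, 2), (0, 1)))[1:3, ::2], [(3, 4)]),
    (lambda a, b: concatenate([a, b], axis=1), [(2, 3), (2, 2)]),
    (lambda a: a.roll((1, -2), (0, 1)), [(3, 5)]),
    (lambda a: nn.softmax(a, axis=-1), [(4, 6)]),
])
def test_primitive_gradients(op, shapes):
    check_op(op, *shapes)


@pytest.mark.parametrize("layer_fn,in_shape", [
    (lambda rng: nn.Linear(5, 3, rng), (4, 5)),
    (lambda rng: nn.Conv1x1(3, 4, rng), (2, 3, 5, 5)),
    (lambda rng: nn.DepthwiseConv2d(3, 3, rng), (2, 3, 6, 6)),
    (lambda rng: nn.Conv2d(3, 4, 3, rng, stride=2, padding=1), (2, 3, 6, 6)),
    (lambda rng: nn.ConvTranspose2d(3, 4, 3, rng, stride=2, padding=1,
                                    output_padding=1), (2, 3, 5, 5)),
    (lambda rng: nn.ConvTranspose2d(3, 2, 4, rng, stride=4), (1, 3, 3, 3)),
    (lambda rng: nn.LayerNorm(4, axis=1), (2, 4, 3, 3)),
])
def test_layer_input_gradients(layer_fn, in_shape):
    rng = np.random.default_rng(3)
    layer = layer_fn(rng)
    x = rng.standard_normal(in_shape)
    w = rng.standard_normal(layer(Tensor(x)).shape)

    def scalar(xv):
        return float((layer(Tensor(xv)) * Tensor(w)).sum())

    t = Tensor(x, requires_grad=True)
    (layer(t) * Tensor(w)).sum().backward()
    num = numeric_grad(scalar, x.copy())
    assert np.abs(t.grad - num).max() < 1e-3


def test_layer_parameter_gradients():
    rng = np.random.default_rng(5)
    layer = nn.Conv2d(2, 3, 3, rng, stride=1, padding=1)
    x = rng.standard_normal((1, 2, 4, 4))
    w = rng.standard_normal((1, 3, 4, 4))
    (layer(Tensor(x)) * Tensor(w)).sum().backward()
    weight = layer.weight
    analytic = weight.grad.copy()

    def scalar(wv):
        weight.data = wv
        return float((layer(Tensor(x)) * Tensor(w)).sum())

    num = numeric_grad(scalar, weight.data.copy().astype(np.float64))
    assert np.abs(analytic - num).max() < 1e-3


def test_conv_transpose_matches_upsample_identity():
    """A stride-2 transposed conv with a delta kernel reproduces zero-stuffed input."""
    rng = np.random.default_rng(0)
    layer = nn.ConvTranspose2d(1, 1, 3, rng, stride=2, padding=1, output_padding=1)
    layer.weight.data[:] = 0.0
    layer.weight.data[0, 0, 1, 1] = 1.0   # identity tap at kernel center
    layer.bias.data[:] = 0.0
    x = rng.standard_normal((1, 1, 4, 4)).astype(np.float32)
    y = layer(Tensor(x)).data
    assert y.shape == (1, 1, 8, 8)
    assert np.allclose(y[0, 0, ::2, ::2], x[0, 0])
    mask = np.ones((8, 8), dtype=bool)
    mask[::2, ::2] = False
    assert np.allclose(y[0, 0][mask], 0.0)


def test_no_grad_suppresses_graph():
    x = Tensor(np.ones(3), requires_grad=True)
    with no_grad():
        y = (x * 2.0).sum()
    assert not y.requires_grad


def test_backward_accumulates_over_reuse():
    x = Tensor(np.array([2.0]), requires_grad=True)
    y = x * x + x * 3.0
    y.sum().backward()
    assert np.allclose(x.grad, [2 * 2.0 + 3.0])
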