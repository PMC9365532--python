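"""Engine-level checks: operator forward semantics against naive loop
implementations and gradients against central finite differences."""

import numpy as np
import pytest

from conftest import naive_conv2d, naive_conv_transpose2d, numeric_gradient
from osteoseg import nn
from osteoseg.nn.tensor import Tensor


@pytest.mark.parametrize("stride,shape", [(1, (2, 5, 6, 3)), (2, (2, 7, 6, 3)),
                                          (2, (1, 8, 8, 2))])
def test_conv2d_matches_naive_loops(rng, stride, shape):
    x = rng.normal(size=shape)
    w = rng.normal(size=(3, 3, shape[-1], 4))
    b = rng.normal(size=4)
    got = nn.conv2d(Tensor(x), Tensor(w), Tensor(b), stride=stride).data
    want = naive_conv2d(x, w, b, stride=stride)
    np.testing.assert_allclose(got, want, atol=1e-12)


def test_conv2d_1x1_pointwise_matches_naive(rng):
    x = rng.normal(size=(2, 4, 5, 3))
    w = rng.normal(size=(1, 1, 3, 6))
    b = rng.normal(size=6)
    got = nn.conv2d(Tensor(x), Tensor(w), Tensor(b)).data
    np.testing.assert_allclose(got, naive_conv2d(x, w, b), atol=1e-12)


def test_conv_transpose_matches_naive_and_doubles(rng):
    x = rng.normal(size=(2, 3, 4, 3))
    w = rng.normal(size=(3, 3, 3, 2))
    b = rng.normal(size=2)
    got = nn.conv_transpose2d(Tensor(x), Tensor(w), Tensor(b))
    assert got.shape == (2, 6, 8, 2)
    np.testing.assert_allclose(got.data, naive_conv_transpose2d(x, w, b),
                               atol=1e-12)


def test_stride2_then_transpose_restores_spatial_dims(rng):
    x = Tensor(rng.normal(size=(1, 8, 8, 3)))
    down = nn.conv2d(x, Tensor(rng.normal(size=(3, 3, 3, 5))), stride=2)
    up = nn.conv_transpose2d(down, Tensor(rng.normal(size=(3, 3, 5, 3))))
    assert down.shape == (1, 4, 4, 5)
    assert up.shape == (1, 8, 8, 3)


def test_ceiling_division_on_odd_input(rng):
    x = Tensor(rng.normal(size=(1, 7, 7, 2)))
    out = nn.conv2d(x, Tensor(rng.normal(size=(3, 3, 2, 3))), stride=2)
    assert out.shape == (1, 4, 4, 3)  # ceil(7/2)


OPS = {
    "conv_s1": lambda t: nn.conv2d(t[0], t[1], t[2], stride=1),
    "conv_s2": lambda t: nn.conv2d(t[0], t[1], t[2], stride=2),
    "convT": lambda t: nn.conv_transpose2d(t[0], t[1], t[2]),
    "maxpool": lambda t: nn.max_pool2(t[0]),
    "avgpool": lambda t: nn.avg_pool2(t[0]),
    "resize": lambda t: nn.bilinear_resize(t[0], (7, 5)),
    "sigmoid": lambda t: nn.sigmoid(t[0]),
    "leaky": lambda t: nn.leaky_relu(t[0], 0.01),
    "concat": lambda t: nn.concat(list(t), axis=-1),
}
ARGS = {
    "conv_s1": [(2, 4, 5, 3), (3, 3, 3, 2), (2,)],
    "conv_s2": [(2, 5, 4, 3), (3, 3, 3, 2), (2,)],
    "convT": [(2, 3, 3, 2), (3, 3, 2, 3), (3,)],
    "maxpool": [(2, 5, 6, 3)],
    "avgpool": [(2, 4, 6, 3)],
    "resize": [(2, 4, 6, 2)],
    "sigmoid": [(3, 4)],
    "leaky": [(3, 4)],
    "concat": [(2, 3, 3, 2), (2, 3, 3, 3)],
}


@pytest.mark.parametrize("name", sorted(OPS))
def test_gradients_match_finite_differences(rng, name):
    arrays = [rng.normal(size=s) for s in ARGS[name]]
    tensors = [Tensor(a, requires_grad=True) for a in arrays]
    out = OPS[name](tensors)
    (out * out).sum().backward()
    for i, a in enumerate(arrays):
        def scalar(xi, i=i):
            repl = [Tensor(x) for x in arrays]
            repl[i] = Tensor(xi)
            o = OPS[name](repl).data
            return float((o * o).sum())
        num = numeric_gradient(scalar, a)
        np.testing.assert_allclose(tensors[i].grad, num, rtol=1e-5, atol=1e-7)


def test_bce_with_logits_value_and_gradient(rng):
    z = rng.normal(size=(3, 4))
    t = (rng.random((3, 4)) > 0.5).astype(float)
    zt = Tensor(z, requires_grad=True)
    loss = nn.bce_with_logits(zt, t)
    # closed form: -t*log(s) - (1-t)*log(1-s)
    s = 1 / (1 + np.exp(-z))
    np.testing.assert_allclose(loss.data, -t * np.log(s) - (1 - t) * np.log1p(-s),
                               atol=1e-10)
    loss.sum().backward()
    np.testing.assert_allclose(zt.grad, s - t, atol=1e-10)


def test_bilinear_resize_preserves_constants(rng):
    x = Tensor(np.full((1, 4, 6, 2), 3.25))
    out = nn.bilinear_resize(x, (9, 5))
    np.testing.assert_allclose(out.data, 3.25, atol=1e-12)


def test_float32_graphs_stay_float32(rng):
    x = Tensor(rng.normal(size=(1, 4, 4, 2)).astype(np.float32), requires_grad=True)
    w = Tensor(rng.normal(size=(3, 3, 2, 2)).astype(np.float32), requires_grad=True)
    out = nn.leaky_relu(nn.conv2d(x, w), 0.01) * 0.5 + 1.0
    assert out.data.dtype == np.float32
    out.sum().backward()
    assert x.grad.dtype == np.float32


def test_dropout_identity_in_eval_and_rate_in_train(rng):
    x = Tensor(np.ones((4, 16, 16, 4)))
    assert nn.dropout(x, 0.2, rng, training=False) is x
    dropped = nn.dropout(Tensor(np.ones((10, 32, 32, 4))), 0.2,
                         np.random.default_rng(0), training=True)
    frac = float(np.mean(dropped.data == 0))
    assert abs(frac - 0.2) < 0.01
    kept = dropped.data[dropped.data != 0]
    np.testing.assert_allclose(kept, 1 / 0.8, atol=1e-12)
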