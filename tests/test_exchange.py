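"""Dual-resolution exchange block: identity behaviour, residual scaling,
channel bookkeeping and a full naive-loop trace of the dense recursion."""

import numpy as np
import pytest

from conftest import naive_conv2d, naive_conv_transpose2d, naive_leaky
from osteoseg.exchange import DualResolutionExchange, ExchangeConfig
from osteoseg.nn.tensor import Tensor


def test_zero_init_block_is_exact_identity_on_both_routes(rng):
    blk = DualResolutionExchange(3, 5, rng=rng)
    blk.zero_init()
    xh = rng.normal(size=(2, 8, 8, 3))
    xl = rng.normal(size=(2, 4, 4, 5))
    oh, ol = blk(Tensor(xh), Tensor(xl))
    np.testing.assert_array_equal(oh.data, xh)
    np.testing.assert_array_equal(ol.data, xl)


def test_residual_scale_combines_deep_and_shallow_paths():
    """O = w*M5 + M0 with the default w = 0.4, checked elementwise."""
    w = ExchangeConfig().residual_scale
    assert w == 0.4
    rng = np.random.default_rng(3)
    a = rng.normal(size=(1, 4, 4, 3))   # stands in for the deep path M5
    b = rng.normal(size=(1, 4, 4, 3))   # stands in for the shallow path M0
    combined = (Tensor(a) * w + Tensor(b)).data
    np.testing.assert_allclose(combined, 0.4 * a + b, atol=1e-12)


def test_zero_residual_scale_reduces_output_to_shallow_path(rng):
    cfg = ExchangeConfig(residual_scale=0.0)
    blk = DualResolutionExchange(2, 3, cfg, rng=rng)
    # zero only the F blocks so M0 = input while the deep path stays random
    blk.f_high.zero_init()
    blk.f_low.zero_init()
    xh = rng.normal(size=(1, 8, 8, 2))
    xl = rng.normal(size=(1, 4, 4, 3))
    oh, ol = blk(Tensor(xh), Tensor(xl))
    np.testing.assert_array_equal(oh.data, xh)
    np.testing.assert_array_equal(ol.data, xl)


def test_concat_channel_arithmetic_per_step(rng):
    """The concat feeding step n must carry n*g_own + g_other channels."""
    g_h, g_l = 3, 5
    blk = DualResolutionExchange(g_h, g_l, rng=rng)
    for n in range(1, 6):
        conv_h = blk.h_high[n - 1].conv.weight.data
        conv_l = blk.h_low[n - 1].conv.weight.data
        assert conv_h.shape[2] == n * g_h + g_l
        assert conv_l.shape[2] == n * g_l + g_h
        assert conv_h.shape[3] == g_h and conv_l.shape[3] == g_l


def test_route_step_rejects_short_history(rng):
    blk = DualResolutionExchange(2, 2, rng=rng)
    x = Tensor(rng.normal(size=(1, 4, 4, 2)))
    with pytest.raises(ValueError, match="histories"):
        blk.route_step(2, [x], [x], "h")


def test_rejects_inputs_not_one_octave_apart(rng):
    blk = DualResolutionExchange(2, 3, rng=rng)
    with pytest.raises(ValueError, match="octave"):
        blk(Tensor(rng.normal(size=(1, 8, 8, 2))),
            Tensor(rng.normal(size=(1, 2, 2, 3))))


def test_output_shapes_match_route_inputs(rng):
    cfg = ExchangeConfig(growth_high=7, growth_low=9)
    blk = DualResolutionExchange(3, 5, cfg, rng=rng)
    oh, ol = blk(Tensor(rng.normal(size=(2, 8, 8, 3))),
                 Tensor(rng.normal(size=(2, 4, 4, 5))))
    assert oh.shape == (2, 8, 8, 3)
    assert ol.shape == (2, 4, 4, 5)


def _naive_h(x, hblock):
    return naive_leaky(naive_conv2d(x, hblock.conv.weight.data,
                                    hblock.conv.bias.data))


def _naive_f(x, fblock):
    return x + _naive_h(_naive_h(x, fblock.h1), fblock.h2)


def test_forward_matches_naive_trace_of_dense_recursion(rng):
    """Re-run the five-step dense exchange with loop convolutions only."""
    blk = DualResolutionExchange(1, 1, rng=rng)
    # randomize biases too so the trace exercises every term
    for p in blk.parameters():
        p.data = rng.normal(size=p.data.shape) * 0.3
    xh = rng.normal(size=(1, 2, 2, 1))
    xl = rng.normal(size=(1, 1, 1, 1))
    got_h, got_l = blk(Tensor(xh), Tensor(xl))

    hist_h = [_naive_f(xh, blk.f_high)]
    hist_l = [_naive_f(xl, blk.f_low)]
    for n in range(1, 6):
        up = naive_conv_transpose2d(hist_l[n - 1], blk.up[n - 1].conv.weight.data,
                                    blk.up[n - 1].conv.bias.data)
        down = naive_conv2d(hist_h[n - 1], blk.down[n - 1].conv.weight.data,
                            blk.down[n - 1].conv.bias.data, stride=2)
        cat_h = np.concatenate([hist_h[n - 1], up]
                               + [hist_h[k] for k in range(n - 2, -1, -1)], axis=-1)
        cat_l = np.concatenate([hist_l[n - 1], down]
                               + [hist_l[k] for k in range(n - 2, -1, -1)], axis=-1)
        hist_h.append(_naive_h(cat_h, blk.h_high[n - 1]))
        hist_l.append(_naive_h(cat_l, blk.h_low[n - 1]))
    want_h = 0.4 * hist_h[5] + hist_h[0]
    want_l = 0.4 * hist_l[5] + hist_l[0]
    np.testing.assert_allclose(got_h.data, want_h, atol=1e-6)
    np.testing.assert_allclose(got_l.data, want_l, atol=1e-6)


def test_growth_factor_projection_restores_route_width(rng):
    cfg = ExchangeConfig(growth_high=16, growth_low=32)
    blk = DualResolutionExchange(4, 8, cfg, rng=rng)
    assert blk.proj_high is not None and blk.proj_low is not None
    oh, ol = blk(Tensor(rng.normal(size=(1, 8, 8, 4))),
                 Tensor(rng.normal(size=(1, 4, 4, 8))))
    assert oh.shape[-1] == 4 and ol.shape[-1] == 8
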