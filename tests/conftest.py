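"""Shared fixtures and independent naive oracles.

The naive convolution routines below are deliberate re-implementations by
explicit loops — slow but transparently correct — used to cross-check the
package's GEMM-based operators and the hand-traceable block equations.
"""

import numpy as np
import pytest


# -- naive reference implementations (loops, no tricks) -------------------

def naive_conv2d(x, w, b=None, stride=1):
    """Direct-loop 2-D convolution, NHWC / (kh, kw, ci, co), zero 'same' pad."""
    n, h, wd, ci = x.shape
    kh, kw, _, co = w.shape
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    oh = (h + 2 * ph - kh) // stride + 1
    ow = (wd + 2 * pw - kw) // stride + 1
    out = np.zeros((n, oh, ow, co))
    for ni in range(n):
        for oi in range(oh):
            for oj in range(ow):
                for u in range(kh):
                    for v in range(kw):
                        ii = oi * stride + u - ph
                        jj = oj * stride + v - pw
                        if 0 <= ii < h and 0 <= jj < wd:
                            out[ni, oi, oj] += x[ni, ii, jj] @ w[u, v]
    if b is not None:
        out += b
    return out


def naive_conv_transpose2d(x, w, b=None):
    """Direct-loop stride-2 transposed convolution (output exactly 2x)."""
    n, h, wd, ci = x.shape
    kh, kw, _, co = w.shape
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    full = np.zeros((n, (h - 1) * 2 + kh, (wd - 1) * 2 + kw, co))
    for ni in range(n):
        for i in range(h):
            for j in range(wd):
                for u in range(kh):
                    for v in range(kw):
                        full[ni, i * 2 + u, j * 2 + v] += x[ni, i, j] @ w[u, v]
    out = full[:, ph : ph + 2 * h, pw : pw + 2 * wd, :]
    if b is not None:
        out = out + b
    return out


def naive_leaky(x, slope=0.01):
    return np.where(x > 0, x, slope * x)


def numeric_gradient(f, x, eps=1e-6):
    """Central finite differences of scalar-valued ``f`` at array ``x``."""
    g = np.zeros_like(x, dtype=float)
    for idx in np.ndindex(x.shape):
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g


# -- fixtures -------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_batch():
    """A small deterministic phantom set shared across tests."""
    from osteoseg import PhantomSpec, generate_dataset

    spec = PhantomSpec(seed=7)
    samples = generate_dataset(spec, 12)
    X = np.stack([s.image for s in samples])
    y = np.stack([s.mask for s in samples])
    return X, y
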