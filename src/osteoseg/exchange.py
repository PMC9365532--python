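"""Dual-resolution feature exchange block.

Two parallel routes process a high- and a low-resolution view of the same
anatomy (one octave apart).  Each route is densely connected: the n-th step
concatenates every earlier map of its own route together with the other
route's previous map, resampled across the octave, and applies an ``H``
convolution whose output width is the route's *growth factor*:

    M_n^s = H( [ M_{n-1}^s, resample(M_{n-1}^s̄), M_{n-2}^s, ..., M_0^s ] )

``M_0^s`` is the route input passed through a residual ``F`` block.  The
block output applies scaled residual learning,

    O^s = w * M_5^s + M_0^s,    w = 0.4 by default,

which stabilizes training by keeping the deep path a perturbation of the
shallow one.  Cross-route resampling is a transposed convolution (``T``)
upward and a stride-2 convolution (``C``) downward, so spatial sizes always
match before concatenation.

With every parameter at zero the block is the exact identity on both routes
(the ``F`` blocks reduce to the identity and the deep path vanishes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import CBlock, FBlock, HBlock, TBlock
from .nn import Conv2d, Module, concat
from .nn.tensor import as_tensor

__all__ = ["ExchangeConfig", "DualResolutionExchange"]


@dataclass
class ExchangeConfig:
    """Hyperparameters of the exchange block.

    ``growth_high`` / ``growth_low`` are the per-step output widths of each
    route's ``H`` structures; ``None`` inherits the route's input width,
    which keeps the residual output well-typed without a projection.
    ``residual_scale`` is the scaling factor ``w`` applied to the deep path.
    """

    growth_high: int | None = None
    growth_low: int | None = None
    n_steps: int = 5
    residual_scale: float = 0.4
    negative_slope: float = 0.01

    def __post_init__(self):
        if not 0.0 <= self.residual_scale <= 1.0:
            raise ValueError("residual_scale must lie in [0, 1]")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


class DualResolutionExchange(Module):
    """Exchange features between one high- and one low-resolution route."""

    def __init__(self, channels_high: int, channels_low: int,
                 config: ExchangeConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = config if config is not None else ExchangeConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = cfg
        self.channels_high = channels_high
        self.channels_low = channels_low
        g_h = cfg.growth_high if cfg.growth_high is not None else channels_high
        g_l = cfg.growth_low if cfg.growth_low is not None else channels_low
        self.growth_high, self.growth_low = g_h, g_l

        ns = cfg.negative_slope
        self.f_high = FBlock(channels_high, rng=rng, negative_slope=ns)
        self.f_low = FBlock(channels_low, rng=rng, negative_slope=ns)

        def hist_ch(route: str, k: int) -> int:
            if k == 0:
                return channels_high if route == "h" else channels_low
            return g_h if route == "h" else g_l

        self.up = []      # low -> high resampler feeding the high route
        self.down = []    # high -> low resampler feeding the low route
        self.h_high = []
        self.h_low = []
        for n in range(1, cfg.n_steps + 1):
            c_l_prev = hist_ch("l", n - 1)
            c_h_prev = hist_ch("h", n - 1)
            self.up.append(TBlock(c_l_prev, c_l_prev, rng=rng, negative_slope=ns))
            self.down.append(CBlock(c_h_prev, c_h_prev, rng=rng, negative_slope=ns))
            in_h = sum(hist_ch("h", k) for k in range(n)) + c_l_prev
            in_l = sum(hist_ch("l", k) for k in range(n)) + c_h_prev
            self.h_high.append(HBlock(in_h, g_h, rng=rng, negative_slope=ns))
            self.h_low.append(HBlock(in_l, g_l, rng=rng, negative_slope=ns))

        self.proj_high = (Conv2d(g_h, channels_high, 1, rng=rng, negative_slope=ns)
                          if g_h != channels_high else None)
        self.proj_low = (Conv2d(g_l, channels_low, 1, rng=rng, negative_slope=ns)
                         if g_l != channels_low else None)

    # -- one dense step ---------------------------------------------------
    def route_step(self, n: int, own_history: list, other_history: list,
                   route: str):
        """Compute ``M_n`` for one route (``route`` in {"h", "l"})."""
        if not 1 <= n <= self.config.n_steps:
            raise ValueError(f"step index must be in [1, {self.config.n_steps}]")
        if len(own_history) < n or len(other_history) < n:
            raise ValueError("route histories are shorter than step index requires")
        resample = self.up[n - 1] if route == "h" else self.down[n - 1]
        conv = self.h_high[n - 1] if route == "h" else self.h_low[n - 1]
        parts = [own_history[n - 1], resample(other_history[n - 1])]
        parts += [own_history[k] for k in range(n - 2, -1, -1)]
        return conv(concat(parts, axis=-1))

    def forward(self, x_high, x_low):
        x_high, x_low = as_tensor(x_high), as_tensor(x_low)
        _, hh, wh, ch = x_high.shape
        _, hl, wl, cl = x_low.shape
        if (hh, wh) != (2 * hl, 2 * wl):
            raise ValueError(
                f"routes must be one octave apart: high {hh}x{wh} vs low {hl}x{wl}")
        if ch != self.channels_high or cl != self.channels_low:
            raise ValueError("route channel counts do not match block construction")

        hist_h = [self.f_high(x_high)]
        hist_l = [self.f_low(x_low)]
        for n in range(1, self.config.n_steps + 1):
            new_h = self.route_step(n, hist_h, hist_l, "h")
            new_l = self.route_step(n, hist_l, hist_h, "l")
            hist_h.append(new_h)
            hist_l.append(new_l)

        deep_h = self.proj_high(hist_h[-1]) if self.proj_high else hist_h[-1]
        deep_l = self.proj_low(hist_l[-1]) if self.proj_low else hist_l[-1]
        w = self.config.residual_scale
        return deep_h * w + hist_h[0], deep_l * w + hist_l[0]
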