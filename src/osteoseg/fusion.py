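"""Multiscale fusion subnetwork.

Four resolution scales (one octave apart) are repeatedly paired into
dual-resolution exchange blocks.  One *layer* runs an exchange block for
every selected pair of scales — all six pairs by default, or the three
adjacent pairs — then fuses each scale's candidate outputs by elementwise
mean followed by a trainable 1x1 projection initialized to the identity.
The subnetwork stacks four such layers and adds the first layer's output to
the original input (a single residual connection), after which every output
scale depends on every input scale.

Pairs that are more than one octave apart reuse the two-route exchange
block unchanged: the higher-resolution member is average-pooled to one
octave above the lower member, and the exchange output is applied back at
native resolution as a bilinearly upsampled residual correction
``x + up(O - pool(x))`` — exactly the identity when the block is, and a
learned cross-scale update otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exchange import DualResolutionExchange, ExchangeConfig
from .nn import Conv2d, Module, avg_pool2, bilinear_resize
from .nn.tensor import as_tensor

__all__ = ["FusionConfig", "MultiscaleFusion", "check_bundle"]


@dataclass
class FusionConfig:
    """Topology of the fusion subnetwork."""

    n_scales: int = 4
    n_layers: int = 4
    pairing: str = "all_pairs"       # or "adjacent"
    exchange: ExchangeConfig = field(default_factory=ExchangeConfig)

    def pairs(self) -> list[tuple[int, int]]:
        idx = range(self.n_scales)
        if self.pairing == "all_pairs":
            return [(a, b) for a in idx for b in idx if a < b]
        if self.pairing == "adjacent":
            return [(a, a + 1) for a in range(self.n_scales - 1)]
        raise ValueError(f"unknown pairing strategy: {self.pairing!r}")


def check_bundle(maps) -> None:
    """Validate a scale bundle: spatial dims halve from scale to scale."""
    prev = None
    for r, m in enumerate(maps):
        m = as_tensor(m)
        _, h, w, _ = m.shape
        if prev is not None and (h, w) != (prev[0] // 2, prev[1] // 2):
            raise ValueError(
                f"scale {r + 1} is {h}x{w}, expected half of {prev[0]}x{prev[1]}")
        prev = (h, w)


def _identity_conv1x1(channels: int) -> Conv2d:
    conv = Conv2d(channels, channels, 1)
    dt = conv.weight.data.dtype
    conv.weight.data = np.eye(channels, dtype=dt).reshape(1, 1, channels, channels)
    conv.bias.data = np.zeros(channels, dtype=dt)
    return conv


class _FusionLayer(Module):
    def __init__(self, widths, cfg: FusionConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.pair_list = cfg.pairs()
        participation = {r for pair in self.pair_list for r in pair}
        if participation != set(range(cfg.n_scales)):
            missing = sorted(set(range(cfg.n_scales)) - participation)
            raise ValueError(f"pairing leaves scales without participation: {missing}")
        self.blocks = [
            DualResolutionExchange(widths[a], widths[b], cfg.exchange, rng=rng)
            for a, b in self.pair_list
        ]
        self.proj = [_identity_conv1x1(w) for w in widths]

    def identity_init(self) -> None:
        """Zero the exchange blocks and reset projections to identity.

        Makes the layer the exact identity map — the reference point the
        residual topology is built around.
        """
        for blk in self.blocks:
            blk.zero_init()
        for conv in self.proj:
            c = conv.weight.data.shape[2]
            dt = conv.weight.data.dtype
            conv.weight.data = np.eye(c, dtype=dt).reshape(1, 1, c, c)
            conv.bias.data = np.zeros(c, dtype=dt)

    def forward(self, bundle):
        bundle = [as_tensor(m) for m in bundle]
        check_bundle(bundle)
        candidates = [[] for _ in bundle]
        for (a, b), block in zip(self.pair_list, self.blocks):
            gap = b - a
            if gap == 1:
                out_h, out_l = block(bundle[a], bundle[b])
                candidates[a].append(out_h)
            else:
                pooled = bundle[a]
                for _ in range(gap - 1):
                    pooled = avg_pool2(pooled)
                out_h, out_l = block(pooled, bundle[b])
                native_hw = bundle[a].shape[1:3]
                corr = bilinear_resize(out_h - pooled, native_hw)
                candidates[a].append(bundle[a] + corr)
            candidates[b].append(out_l)
        fused = []
        for r, cands in enumerate(candidates):
            acc = cands[0]
            for extra in cands[1:]:
                acc = acc + extra
            fused.append(self.proj[r](acc * (1.0 / len(cands))))
        return fused


class MultiscaleFusion(Module):
    """Stack of fusion layers with a first-layer residual connection."""

    def __init__(self, widths, config: FusionConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = config if config is not None else FusionConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        if len(widths) != cfg.n_scales:
            raise ValueError(
                f"expected {cfg.n_scales} scale widths, got {len(widths)}")
        self.config = cfg
        self.widths = tuple(widths)
        self.layers = [_FusionLayer(widths, cfg, rng) for _ in range(cfg.n_layers)]

    def identity_init(self) -> None:
        """Make every layer the exact identity (zeroed exchange blocks)."""
        for layer in self.layers:
            layer.identity_init()

    def forward(self, bundle):
        bundle = [as_tensor(m) for m in bundle]
        check_bundle(bundle)
        x = self.layers[0](bundle)
        # single residual connection: layer-1 output plus the subnet input
        x = [xi + bi for xi, bi in zip(x, bundle)]
        for layer in self.layers[1:]:
            x = layer(x)
        return x
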