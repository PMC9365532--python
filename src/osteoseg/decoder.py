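"""Decoder blocks: spatial+channel attention combined with an attention gate.

Each decoder block receives an encoder-side skip feature and the previous
(coarser) decoder output ``P`` and produces features at the skip's
resolution:

* spatial+channel attention ``A_SC = (SE + 1)(x) ⊙ M`` — a residual
  squeeze-and-excitation rescaling multiplied by a single-channel sigmoid
  spatial mask replicated across channels;
* an additive attention gate ``A_AG`` — coefficients
  ``sigmoid(Conv1x1(phi(skip) + psi(P)))`` computed at ``P``'s resolution,
  upsampled to the skip's resolution, applied to the skip by Hadamard
  product, then concatenated with the upsampled ``T(P)``;
* the two branches are concatenated (``A_SCC = A_SC ⌒ A_AG``) and passed
  through two ``H`` convolutions.

The gate coefficients suppress skip activations that are irrelevant to the
predicted tumor region. Coefficient maps are upsampled bilinearly so their
values provably stay inside (0, 1).
"""

from __future__ import annotations

import numpy as np

from .blocks import HBlock, SEBlock
from .nn import Conv2d, ConvTranspose2d, Module, bilinear_resize, concat, leaky_relu, sigmoid
from .nn.tensor import as_tensor

__all__ = ["SpatialChannelAttention", "AttentionGate", "DecoderBlock"]


class SpatialChannelAttention(Module):
    """``(SE + 1)(x) ⊙ M`` — residual channel gating under a spatial mask."""

    def __init__(self, channels: int, se_reduction: int = 8,
                 rng: np.random.Generator | None = None,
                 negative_slope: float = 0.01):
        super().__init__()
        self.se = SEBlock(channels, reduction=se_reduction, rng=rng,
                          negative_slope=negative_slope)
        self.spatial = Conv2d(channels, 1, 1, rng=rng,
                              negative_slope=negative_slope)

    def spatial_mask(self, x):
        """Single-channel sigmoid mask, broadcast across all channels."""
        return sigmoid(self.spatial(as_tensor(x)))

    def forward(self, x):
        x = as_tensor(x)
        m = self.spatial_mask(x)
        return (self.se(x) + x) * m


class AttentionGate(Module):
    """Additive attention gate between a skip path and a coarser feature."""

    def __init__(self, skip_channels: int, p_channels: int,
                 rng: np.random.Generator | None = None,
                 negative_slope: float = 0.01):
        super().__init__()
        # phi: stride-2 1x1 conv bringing the skip to P's resolution
        self.phi = Conv2d(skip_channels, skip_channels, 1, stride=2, rng=rng,
                          negative_slope=negative_slope)
        # psi: stride-1 1x1 conv aligning P's channels with phi's output
        self.psi = Conv2d(p_channels, skip_channels, 1, rng=rng,
                          negative_slope=negative_slope)
        self.att = Conv2d(skip_channels, 1, 1, rng=rng,
                          negative_slope=negative_slope)
        self.up = ConvTranspose2d(p_channels, skip_channels, 3, rng=rng,
                                  negative_slope=negative_slope)
        self.negative_slope = negative_slope

    def coefficients(self, skip, p):
        """Gate coefficients in (0, 1) at the skip's resolution."""
        skip, p = as_tensor(skip), as_tensor(p)
        _, hs, ws, _ = skip.shape
        _, hp, wp, _ = p.shape
        if (hs, ws) != (2 * hp, 2 * wp):
            raise ValueError(
                f"skip must be exactly one octave finer than P: {hs}x{ws} vs {hp}x{wp}")
        q = leaky_relu(self.phi(skip) + self.psi(p), self.negative_slope)
        coeff = sigmoid(self.att(q))
        return bilinear_resize(coeff, (hs, ws))

    def forward(self, skip, p):
        skip, p = as_tensor(skip), as_tensor(p)
        coeff = self.coefficients(skip, p)
        gated = skip * coeff
        return concat([gated, self.up(p)], axis=-1)


class DecoderBlock(Module):
    """One decoder stage at the skip's resolution.

    Output channels follow ``out_channels``; the internal concatenation has
    ``3 * skip_channels`` channels (attention branch: ``skip``, gate branch:
    ``skip + skip`` from the gated skip and the upsampled ``T(P)``).
    """

    def __init__(self, skip_channels: int, p_channels: int, out_channels: int,
                 se_reduction: int = 8, rng: np.random.Generator | None = None,
                 negative_slope: float = 0.01):
        super().__init__()
        self.sca = SpatialChannelAttention(skip_channels, se_reduction, rng=rng,
                                           negative_slope=negative_slope)
        self.gate = AttentionGate(skip_channels, p_channels, rng=rng,
                                  negative_slope=negative_slope)
        self.h1 = HBlock(3 * skip_channels, out_channels, rng=rng,
                         negative_slope=negative_slope)
        self.h2 = HBlock(out_channels, out_channels, rng=rng,
                         negative_slope=negative_slope)

    def forward(self, skip, p):
        combined = concat([self.sca(skip), self.gate(skip, p)], axis=-1)
        return self.h2(self.h1(combined))
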