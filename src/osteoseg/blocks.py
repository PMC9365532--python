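"""The five layer primitives every other block is assembled from.

* ``H`` — 3x3 "same" convolution followed by LeakyReLU.
* ``C`` — 3x3 stride-2 convolution (spatial halving, ceiling division).
* ``T`` — 3x3 stride-2 transposed convolution (exact spatial doubling).
* ``F`` — residual block, ``x + H(H(x))``; the identity map at zero init.
* ``SE`` — squeeze-and-excitation channel gating: global average pool, a
  two-layer bottleneck (LeakyReLU then sigmoid), per-channel multipliers.

Blocks operate on rank-4 ``(batch, height, width, channels)`` tensors. They
also accept a :class:`FeatureMap`, in which case the resolution-scale index
is propagated (``C`` moves one scale coarser, ``T`` one finer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Conv2d, ConvTranspose2d, Linear, Module
from .nn.tensor import Tensor, as_tensor

__all__ = ["BlockParams", "FeatureMap", "HBlock", "CBlock", "TBlock",
           "FBlock", "SEBlock"]


@dataclass
class BlockParams:
    """Shared hyperparameters of the layer primitives."""

    out_channels: int
    negative_slope: float = 0.01
    se_reduction: int = 8

    def __post_init__(self):
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")


@dataclass
class FeatureMap:
    """A rank-4 feature tensor tagged with its resolution-scale index.

    ``scale`` counts octaves from the finest resolution (1 = full input
    resolution, 2 = half, ...).
    """

    values: Tensor
    scale: int = 1

    def __post_init__(self):
        self.values = as_tensor(self.values)
        if self.values.ndim != 4:
            raise ValueError(f"expected a rank-4 array, got rank {self.values.ndim}")
        if not np.all(np.isfinite(self.values.data)):
            raise ValueError("feature map contains non-finite values")

    @property
    def shape(self):
        return self.values.shape


class _ScaleAware(Module):
    """Dispatch helper so blocks accept Tensors or FeatureMaps."""

    scale_delta = 0

    def __call__(self, x, *args, **kwargs):
        if isinstance(x, FeatureMap):
            out = self.forward(x.values, *args, **kwargs)
            return FeatureMap(out, scale=x.scale + self.scale_delta)
        return self.forward(x, *args, **kwargs)


class HBlock(_ScaleAware):
    """3x3 same-padding convolution + LeakyReLU (spatial size preserved)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None,
                 negative_slope: float = 0.01):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, 3, rng=rng,
                           negative_slope=negative_slope)
        self.negative_slope = negative_slope

    def forward(self, x):
        return nn.leaky_relu(self.conv(x), self.negative_slope)


class CBlock(_ScaleAware):
    """3x3 stride-2 convolution; output spatial dims are ``ceil(in/2)``."""

    scale_delta = +1

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None,
                 negative_slope: float = 0.01):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, 3, stride=2, rng=rng,
                           negative_slope=negative_slope)

    def forward(self, x):
        x = as_tensor(x)
        _, h, w, _ = x.shape
        if h < 2 or w < 2:
            raise ValueError(f"stride-2 convolution needs spatial dims >= 2, got {h}x{w}")
        return self.conv(x)


class TBlock(_ScaleAware):
    """3x3 stride-2 transposed convolution; output is exactly 2x the input."""

    scale_delta = -1

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None,
                 negative_slope: float = 0.01):
        super().__init__()
        self.conv = ConvTranspose2d(in_channels, out_channels, 3, rng=rng,
                                    negative_slope=negative_slope)

    def forward(self, x):
        return self.conv(x)


class FBlock(_ScaleAware):
    """Residual block ``x + H(H(x))``; exactly the identity at zero init."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None,
                 negative_slope: float = 0.01):
        super().__init__()
        self.h1 = HBlock(channels, channels, rng=rng, negative_slope=negative_slope)
        self.h2 = HBlock(channels, channels, rng=rng, negative_slope=negative_slope)
        self.channels = channels

    def forward(self, x):
        x = as_tensor(x)
        if x.shape[-1] != self.channels:
            raise ValueError(
                f"residual skip needs {self.channels} channels, got {x.shape[-1]}")
        return x + self.h2(self.h1(x))


class SEBlock(_ScaleAware):
    """Squeeze-and-excitation: rescale each channel by a gate in (0, 1)."""

    def __init__(self, channels: int, reduction: int = 8,
                 rng: np.random.Generator | None = None,
                 negative_slope: float = 0.01):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng=rng, negative_slope=negative_slope)
        self.fc2 = Linear(hidden, channels, rng=rng, negative_slope=negative_slope)
        self.negative_slope = negative_slope

    def gates(self, x) -> Tensor:
        """Per-channel gates, shape ``(batch, 1, 1, channels)``."""
        x = as_tensor(x)
        squeezed = x.mean(axis=(1, 2))                       # (N, C)
        z = nn.leaky_relu(self.fc1(squeezed), self.negative_slope)
        g = nn.sigmoid(self.fc2(z))
        n, c = g.shape
        return g.reshape(n, 1, 1, c)

    def forward(self, x):
        x = as_tensor(x)
        return x * self.gates(x)
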